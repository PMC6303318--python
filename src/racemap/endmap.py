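"""Templated 3′-end assignment and non-templated-addition calling.

The end of each linker-trimmed insert is placed on the reference by
anchored suffix matching: the 20 nt closest to the insert's 3′ end are
slid over the reference, tolerating up to two substitutions except at
the two most-3′ anchor positions, which must match exactly. If no
placement exists, one insert base is trimmed off as a putative
non-templated addition and the search repeats. The call is the smallest
such trim with a valid placement; among in-window placements at that
trim, the most 3′ reference coordinate wins. Trimmed bases are reported
as the non-templated nucleotide addition (NTNA) — in this system
predominantly oligo-A added by PAPD5/TRAMP.

Consequence worth knowing: tail bases that happen to match the reference
continuation past the true end are absorbed as templated sequence, so
the assigned coordinate is an upper bound on the true end. That is
inherent to calling the *most 3′* templated coordinate and is shared by
the naive oracle.

``oracle_assign_end`` is a deliberately naive re-implementation
(exhaustive enumeration of every (trim, coordinate) pair with direct
Hamming comparison) kept as an independent check on the vectorized path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .refmodel import ReferenceModel

DEFAULT_ANCHOR_LEN = 20
DEFAULT_MAX_MISMATCH = 2
DEFAULT_EXACT_TERMINAL = 2

# end-call statuses
ASSIGNED = "assigned"
NO_LINKER = "no_linker"
SHORT_MATCH = "short_match"
NO_ANCHOR = "no_anchor"
OUT_OF_WINDOW = "out_of_window"
STATUSES = (ASSIGNED, NO_LINKER, SHORT_MATCH, NO_ANCHOR, OUT_OF_WINDOW)

_VALID = frozenset("ACGT")


@dataclass
class EndCall:
    """Per-read end-assignment result.

    When ``status == "assigned"``: ``end_coord`` is the 1-based reference
    coordinate of the last templated base, ``ntna`` the trimmed
    non-templated suffix (``tail_trim == len(ntna)``), and
    ``anchor_mismatches`` the substitutions accepted in the anchor.
    """

    read_id: str | None
    status: str
    end_coord: int | None = None
    ntna: str = ""
    anchor_mismatches: int | None = None
    tail_trim: int | None = None


def _check_insert(insert: str) -> str:
    insert = insert.upper()
    if set(insert) - _VALID:
        bad = sorted(set(insert) - _VALID)
        raise ValueError(f"insert contains non-ACGT characters: {bad!r}")
    return insert


def assign_end(
    insert: str,
    model: ReferenceModel,
    anchor_len: int = DEFAULT_ANCHOR_LEN,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    exact_terminal: int = DEFAULT_EXACT_TERMINAL,
    max_tail: int | None = None,
    terminal_free: bool = False,
    read_id: str | None = None,
) -> EndCall:
    """Assign the templated 3′-end coordinate of one insert.

    Parameters mirror the matching rule: ``anchor_len`` bases nearest the
    3′ end are matched with at most ``max_mismatch`` substitutions, the
    ``exact_terminal`` most-3′ anchor bases matching exactly. With
    ``terminal_free=True`` the alternative reading is used instead: the
    terminal bases may mismatch freely and are simply not counted.
    ``max_tail`` caps how many bases may be trimmed as NTNA (default: as
    many as the insert allows while keeping a full anchor).

    Statuses: ``assigned``; ``short_match`` (insert shorter than the
    anchor, realizing the minimum-match filter); ``no_anchor`` (no valid
    placement at any trim); ``out_of_window`` (valid placements exist at
    the chosen trim but only outside the assignment window).
    """
    if anchor_len < exact_terminal:
        raise ValueError("anchor_len must be >= exact_terminal")
    insert = _check_insert(insert)
    n = len(insert)
    if n < anchor_len:
        return EndCall(read_id, SHORT_MATCH)

    limit = n - anchor_len
    if max_tail is not None:
        limit = min(limit, max_tail)

    codes = np.frombuffer(insert.encode("ascii"), dtype=np.uint8)
    windows = model.anchor_windows(anchor_len)  # row i ends at coord i + anchor_len
    ws, we = model.window

    for t in range(limit + 1):
        anchor = codes[n - t - anchor_len : n - t]
        neq = windows != anchor
        if exact_terminal > 0:
            body_mm = neq[:, : anchor_len - exact_terminal].sum(axis=1)
            if terminal_free:
                valid = body_mm <= max_mismatch
            else:
                terminal_ok = ~neq[:, anchor_len - exact_terminal :].any(axis=1)
                valid = terminal_ok & (body_mm <= max_mismatch)
        else:
            body_mm = neq.sum(axis=1)
            valid = body_mm <= max_mismatch
        hits = np.nonzero(valid)[0]
        if hits.size == 0:
            continue
        ends = hits + anchor_len  # 1-based end coordinates
        in_window = ends[(ends >= ws) & (ends <= we)]
        if in_window.size == 0:
            return EndCall(read_id, OUT_OF_WINDOW, tail_trim=t)
        e = int(in_window.max())
        return EndCall(
            read_id,
            ASSIGNED,
            end_coord=e,
            ntna=insert[n - t :],
            anchor_mismatches=int(body_mm[e - anchor_len]),
            tail_trim=t,
        )
    return EndCall(read_id, NO_ANCHOR)


def oracle_assign_end(
    insert: str,
    model: ReferenceModel,
    anchor_len: int = DEFAULT_ANCHOR_LEN,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    exact_terminal: int = DEFAULT_EXACT_TERMINAL,
    max_tail: int | None = None,
    terminal_free: bool = False,
    read_id: str | None = None,
) -> EndCall:
    """Naive reference implementation of :func:`assign_end`.

    Enumerates every (tail_trim, end coordinate) pair over the whole
    reference and compares base by base; intentionally free of the
    vectorized path's machinery so the two can check each other.
    """
    if anchor_len < exact_terminal:
        raise ValueError("anchor_len must be >= exact_terminal")
    insert = _check_insert(insert)
    n = len(insert)
    if n < anchor_len:
        return EndCall(read_id, SHORT_MATCH)
    limit = n - anchor_len
    if max_tail is not None:
        limit = min(limit, max_tail)
    ref = model.sequence
    ws, we = model.window
    body = anchor_len - exact_terminal

    for t in range(limit + 1):
        anchor = insert[n - t - anchor_len : n - t]
        matches: list[tuple[int, int]] = []  # (end coord, body mismatches)
        for e in range(anchor_len, len(ref) + 1):
            seg = ref[e - anchor_len : e]
            body_mm = sum(a != b for a, b in zip(anchor[:body], seg[:body]))
            term_mm = sum(a != b for a, b in zip(anchor[body:], seg[body:]))
            if terminal_free or exact_terminal == 0:
                ok = body_mm + (term_mm if exact_terminal == 0 else 0) <= max_mismatch
            else:
                ok = term_mm == 0 and body_mm <= max_mismatch
            if ok:
                matches.append((e, body_mm))
        if matches:
            in_window = [(e, mm) for e, mm in matches if ws <= e <= we]
            if not in_window:
                return EndCall(read_id, OUT_OF_WINDOW, tail_trim=t)
            e, mm = max(in_window)
            return EndCall(
                read_id, ASSIGNED, end_coord=e, ntna=insert[n - t :],
                anchor_mismatches=mm, tail_trim=t,
            )
    return EndCall(read_id, NO_ANCHOR)


def assign_ends(reads, model: ReferenceModel, **params) -> list[EndCall]:
    """Run :func:`assign_end` over preprocessed reads.

    Accepts :class:`~racemap.preprocess.ReadRecord` objects (reads whose
    linker was never located become ``no_linker`` calls) or raw insert
    strings.
    """
    calls = []
    for r in reads:
        if isinstance(r, str):
            calls.append(assign_end(r, model, **params))
        elif r.insert is None:
            calls.append(EndCall(r.id, NO_LINKER))
        else:
            calls.append(assign_end(r.insert, model, read_id=r.id, **params))
    return calls


def tail_composition(call: EndCall) -> tuple[dict[str, int], bool]:
    """Per-base counts of the NTNA and whether it is pure oligo-A.

    ``pure_A`` is True only for a nonempty all-A tail. Raises on
    unassigned calls.
    """
    if call.status != ASSIGNED:
        raise ValueError(f"tail_composition needs an assigned call, got {call.status!r}")
    counts = {b: call.ntna.count(b) for b in "ACGT"}
    pure_a = bool(call.ntna) and counts["A"] == len(call.ntna)
    return counts, pure_a


def calls_to_frame(calls) -> pd.DataFrame:
    """EndCall table as a DataFrame (TSV-ready)."""
    return pd.DataFrame(
        [
            (c.read_id, c.status, c.end_coord, c.ntna, c.tail_trim, c.anchor_mismatches)
            for c in calls
        ],
        columns=["read_id", "status", "end_coord", "ntna", "tail_trim", "anchor_mismatches"],
    )


def write_calls(calls, path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def _opt_int(x) -> int | None:
    if x in ("", None) or pd.isna(x):
        return None
    return int(float(x))


def read_calls(path) -> list[EndCall]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        EndCall(
            str(row.read_id),
            row.status,
            _opt_int(row.end_coord),
            str(row.ntna),
            _opt_int(row.anchor_mismatches),
            _opt_int(row.tail_trim),
        )
        for row in df.itertuples(index=False)
    ]
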