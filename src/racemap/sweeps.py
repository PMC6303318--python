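"""Behavioral parameter sweeps on synthetic reads.

Each sweep constructs error-free reads with a controlled property
(true end coordinate, templated length, linker truncation), pushes them
through the real pipeline stages, and reads the effective parameter or
boundary off the observed behavior: where the mature/exS/exL class
edges fall, the largest coordinate the end-mapper will assign, the
minimum templated match, and the minimum linker match. They double as
executable documentation of the defaults.
"""

from __future__ import annotations

from .refmodel import ReferenceModel
from .preprocess import ReadRecord, process_reads
from .endmap import ASSIGNED, OUT_OF_WINDOW, assign_end, assign_ends

_SWEEP_BARCODE = "ACGTACGTAC"


def _sweep_read(model: ReferenceModel, end_coord: int, templated_len: int = 60) -> ReadRecord:
    from .simulate import build_read_sequence

    bases = build_read_sequence(
        model, end_coord, templated_len=templated_len, barcode=_SWEEP_BARCODE
    )
    return ReadRecord(id=f"end{end_coord}", bases=bases)


def classification_sweep(model: ReferenceModel) -> dict[int, str]:
    """One error-free, tail-free read per window coordinate, through
    linker location and end assignment; returns {assigned coord: label}."""
    ws, we = model.window
    reads = [_sweep_read(model, c) for c in range(ws, we + 1)]
    with_linker, no_linker = process_reads(reads, model)
    calls = assign_ends(with_linker, model)
    out: dict[int, str] = {}
    for call in calls:
        if call.status == ASSIGNED:
            out[call.end_coord] = model.classify(call.end_coord)
    return out


def class_boundary(labels: dict[int, str], label: str, side: str) -> int:
    coords = [c for c, l in labels.items() if l == label]
    if not coords:
        raise ValueError(f"no coordinate classified {label!r}")
    return min(coords) if side == "min" else max(coords)


def window_ceiling_sweep(model: ReferenceModel, lo: int = 600, hi: int = 700) -> int:
    """Reads ending at each coordinate in [lo, hi]; returns the maximum
    assigned coordinate. Ends beyond the window must come back
    out_of_window, never silently clamped."""
    assigned: list[int] = []
    for c in range(lo, min(hi, len(model.sequence)) + 1):
        read = _sweep_read(model, c)
        with_linker, _ = process_reads([read], model)
        calls = assign_ends(with_linker, model)
        call = calls[0]
        if call.status == ASSIGNED:
            assigned.append(call.end_coord)
        elif call.status != OUT_OF_WINDOW:
            raise AssertionError(
                f"read ending at {c}: unexpected status {call.status!r}"
            )
    return max(assigned)


def min_templated_length_sweep(
    model: ReferenceModel, end_coord: int | None = None, lo: int = 10, hi: int = 30
) -> int:
    """Smallest templated insert length that yields an assigned call."""
    end_coord = model.mature_end if end_coord is None else end_coord
    smallest = None
    for length in range(lo, hi + 1):
        insert = model.sequence[end_coord - length : end_coord]
        call = assign_end(insert, model)
        if call.status == ASSIGNED and smallest is None:
            smallest = length
    if smallest is None:
        raise ValueError("no length in the sweep yielded an assigned call")
    return smallest


def min_linker_match_sweep(model: ReferenceModel, lo: int = 5, hi: int = 15) -> int:
    """Smallest linker-prefix truncation at which the linker is located."""
    from .simulate import build_read_sequence
    from .preprocess import locate_linker

    smallest = None
    for k in range(lo, hi + 1):
        bases = build_read_sequence(
            model, model.mature_end, templated_len=60, linker_prefix_len=k
        )
        if locate_linker(bases, model) is not None and smallest is None:
            smallest = k
    if smallest is None:
        raise ValueError("linker never located in the sweep")
    return smallest
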