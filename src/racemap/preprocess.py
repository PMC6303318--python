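"""Linker location, molecular-barcode extraction and PCR deduplication.

The 3′ linker is the constant adapter ligated to every RNA 3′ end; a
read is usable only if a sufficiently long exact prefix of the linker is
found (default 10 nt). Everything 5′ of the linker is the insert (the
templated transcript suffix plus any non-templated tail). The 10-nt
randomized molecular barcode that identifies the original molecule sits
3′ of the constant linker; reads sharing (barcode, insert) are PCR
duplicates and are collapsed to a single representative.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .refmodel import ReferenceModel

DEFAULT_LINKER_MIN_MATCH = 10
DEFAULT_BARCODE_LEN = 10


@dataclass
class ReadRecord:
    """One sequencing read, annotated in place as it moves through the
    pipeline: ``linker_offset``/``insert`` after linker location,
    ``barcode`` after extraction, ``family_size`` after deduplication."""

    id: str
    bases: str
    qualities: str | None = None
    barcode: str | None = None
    insert: str | None = None
    linker_offset: int | None = None
    family_size: int | None = None


def locate_linker(
    read: ReadRecord | str,
    model: ReferenceModel,
    min_match: int = DEFAULT_LINKER_MIN_MATCH,
    max_mismatch: int = 0,
) -> int | None:
    """Smallest 0-based offset where the first ``min_match`` linker bases
    match the read; ``None`` when absent.

    Matching is exact by default (``max_mismatch=0``); a mismatch-tolerant
    scan is available but off by default. The 5′-most hit wins, giving the
    shorter, conservative insert.
    """
    if min_match > len(model.linker):
        raise ValueError(
            f"min_match {min_match} exceeds linker length {len(model.linker)}"
        )
    bases = read.bases if isinstance(read, ReadRecord) else read
    probe = model.linker[:min_match]
    if max_mismatch == 0:
        off = bases.find(probe)
        return None if off < 0 else off
    for off in range(len(bases) - min_match + 1):
        mm = sum(a != b for a, b in zip(bases[off : off + min_match], probe))
        if mm <= max_mismatch:
            return off
    return None


def extract_barcode(
    read: ReadRecord | str,
    linker_offset: int,
    linker_len: int,
    barcode_len: int = DEFAULT_BARCODE_LEN,
) -> str | None:
    """The ``barcode_len`` bases immediately 3′ of the full linker.

    ``linker_len`` is the length of the constant linker present in the
    read (callers pass ``len(model.linker)``). Reads truncated before a
    complete barcode yield ``None``; such reads are retained downstream
    but excluded from duplicate collapsing.
    """
    bases = read.bases if isinstance(read, ReadRecord) else read
    start = linker_offset + linker_len
    end = start + barcode_len
    if end > len(bases):
        return None
    return bases[start:end]


def process_reads(
    reads,
    model: ReferenceModel,
    min_match: int = DEFAULT_LINKER_MIN_MATCH,
    barcode_len: int = DEFAULT_BARCODE_LEN,
    linker_max_mismatch: int = 0,
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Annotate reads with linker offset, insert and barcode.

    Returns ``(with_linker, no_linker)``; reads without a locatable
    linker carry no insert and are counted as filter failures downstream.
    """
    with_linker: list[ReadRecord] = []
    no_linker: list[ReadRecord] = []
    for read in reads:
        off = locate_linker(read, model, min_match=min_match, max_mismatch=linker_max_mismatch)
        if off is None:
            no_linker.append(read)
            continue
        read.linker_offset = off
        read.insert = read.bases[:off]
        read.barcode = extract_barcode(read, off, len(model.linker), barcode_len)
        with_linker.append(read)
    return with_linker, no_linker


def deduplicate(reads) -> list[ReadRecord]:
    """Collapse PCR duplicates on the (barcode, insert) key.

    Exactly one representative (the first seen, input order preserved) is
    retained per key; its ``family_size`` is the number collapsed. Reads
    without a barcode pass through unchanged with ``family_size`` 1.
    Distinct molecules can share a 10-nt barcode by chance, so the full
    insert sequence is part of the key rather than the barcode alone.
    """
    kept: dict[tuple[str, str], ReadRecord] = {}
    passthrough: list[tuple[int, ReadRecord]] = []
    order: dict[tuple[str, str], int] = {}
    for i, read in enumerate(reads):
        if read.barcode is None:
            read.family_size = 1
            passthrough.append((i, read))
            continue
        key = (read.barcode, read.insert if read.insert is not None else read.bases)
        if key in kept:
            kept[key].family_size += 1
        else:
            read.family_size = 1
            kept[key] = read
            order[key] = i
    merged = [(order[k], r) for k, r in kept.items()] + passthrough
    merged.sort(key=lambda t: t[0])
    return [r for _, r in merged]


def preprocess_log(with_linker, no_linker) -> pd.DataFrame:
    """Per-read log: linker offset, barcode, dedup family size."""
    rows = [
        (r.id, r.linker_offset, r.barcode if r.barcode is not None else "",
         r.family_size if r.family_size is not None else "")
        for r in with_linker
    ] + [(r.id, "", "", "") for r in no_linker]
    return pd.DataFrame(rows, columns=["read_id", "linker_offset", "barcode", "family_size"])
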