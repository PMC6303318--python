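"""End-to-end orchestration: FASTQ → end calls → distribution."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .refmodel import ReferenceModel
from . import preprocess, endmap, summarize
from .simulate import read_fastq


@dataclass
class PipelineParams:
    """All tunables of the read-level pipeline in one place."""

    linker_min_match: int = preprocess.DEFAULT_LINKER_MIN_MATCH
    linker_max_mismatch: int = 0
    barcode_len: int = preprocess.DEFAULT_BARCODE_LEN
    anchor_len: int = endmap.DEFAULT_ANCHOR_LEN
    max_mismatch: int = endmap.DEFAULT_MAX_MISMATCH
    exact_terminal: int = endmap.DEFAULT_EXACT_TERMINAL
    terminal_free: bool = False
    max_tail: int | None = None
    deduplicate: bool = True


@dataclass
class SampleResult:
    sample: str
    calls: list
    distribution: summarize.EndDistribution
    log: pd.DataFrame


def run_reads(
    reads,
    model: ReferenceModel,
    sample: str = "sample",
    params: PipelineParams | None = None,
) -> SampleResult:
    """Run preprocessing, deduplication, end assignment and tallying on
    in-memory reads; reads failing the linker filter become ``no_linker``
    calls so the distribution accounts for every input read."""
    p = params or PipelineParams()
    with_linker, no_linker = preprocess.process_reads(
        reads,
        model,
        min_match=p.linker_min_match,
        barcode_len=p.barcode_len,
        linker_max_mismatch=p.linker_max_mismatch,
    )
    if p.deduplicate:
        with_linker = preprocess.deduplicate(with_linker)
    calls = endmap.assign_ends(
        list(with_linker) + list(no_linker),
        model,
        anchor_len=p.anchor_len,
        max_mismatch=p.max_mismatch,
        exact_terminal=p.exact_terminal,
        terminal_free=p.terminal_free,
        max_tail=p.max_tail,
    )
    dist = summarize.tally(calls, model, sample)
    log = preprocess.preprocess_log(with_linker, no_linker)
    return SampleResult(sample, calls, dist, log)


def run_fastq(
    path,
    model: ReferenceModel,
    sample: str = "sample",
    params: PipelineParams | None = None,
) -> SampleResult:
    """As :func:`run_reads`, reading 4-line FASTQ (gzip accepted)."""
    return run_reads(read_fastq(path), model, sample=sample, params=params)
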