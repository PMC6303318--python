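"""Synthetic RLM-RACE library generation with known ground truth.

Emulates the structure of a ligase-mediated 3′-RACE deep-sequencing
library for a single transcript: each molecule is a templated suffix of
the reference ending at a drawn 3′ coordinate, optionally carrying a
non-templated tail (predominantly oligo-A), followed by the constant 3′
linker, a randomized molecular barcode (UMI), and random filler out to
the read length. Molecules are amplified into exact PCR copies sharing
one barcode, and uniform substitution errors are applied. A truth table
records, per molecule, the true end coordinate, tail, barcode and copy
number so every downstream stage can be checked against ground truth.

Approximations relative to a real library (see also the package docs):
no indels, no quality-dependent errors, constant high base qualities
(the analysis is match-based and never consults qualities), and the
barcode is placed 3′ of the full constant linker.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .refmodel import ReferenceModel, build_reference

#: fixed synthetic 3′ adapter used when no real linker is supplied (25 nt)
DEFAULT_LINKER = "CTGTAGGCACCATCAATCGTATGCC"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: default study-condition mixture of 3′-isoform classes
DEFAULT_CLASS_FRACTIONS = {"sub_mature": 0.05, "mature": 0.55, "exS": 0.25, "exL": 0.15}


def random_reference(length: int, seed: int, linker: str = DEFAULT_LINKER, **overrides) -> ReferenceModel:
    """Uniform-random A/C/G/T reference of ``length`` nt with the default
    linker; deterministic for a given seed."""
    window_end = overrides.get("window_end", 641)
    if length < window_end:
        raise ValueError(f"length {length} < window_end {window_end}")
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=length).tobytes().decode("ascii")
    return build_reference(seq, linker, **overrides)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic library.

    ``end_distribution`` maps 1-based end coordinates to probabilities
    (must sum to 1 over the model window); if ``None``, a default mixture
    over isoform classes is used (5% sub-mature, 55% mature, 25% exS,
    15% exL, spread uniformly within each class interval). Tail lengths
    are geometric (support >= 1) with the stated mean, capped; tails are
    pure A except for an optional per-base non-A rate. PCR copy numbers
    are geometric with the stated mean. Substitution errors are applied
    per molecule before copying, so copies are exact duplicates.
    """

    n_molecules: int = 10_000
    end_distribution: dict[int, float] | None = None
    tail_prob: float = 0.5
    tail_mean: float = 5.0
    tail_cap: int = 30
    tail_non_a_rate: float = 0.0
    barcode_len: int = 10
    error_rate: float = 0.001
    dup_mean: float = 2.0
    read_len: int = 250
    templated_len_range: tuple[int, int] = (40, 120)
    seed: int = 0
    post_copy_errors: bool = False

    def validate(self, model: ReferenceModel) -> None:
        if self.n_molecules < 0:
            raise ValueError("n_molecules must be >= 0")
        for p in (self.tail_prob, self.tail_non_a_rate, self.error_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.tail_mean < 1 or self.dup_mean < 1:
            raise ValueError("geometric means must be >= 1")
        dist = self.resolved_end_distribution(model)
        lo, hi = model.window
        if any(not (lo <= c <= hi) for c in dist):
            raise ValueError("end_distribution has mass outside the model window")
        total = sum(dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"end_distribution sums to {total}, not 1")
        if any(not (0.0 <= p <= 1.0) for p in dist.values()):
            raise ValueError("end_distribution probabilities outside [0, 1]")
        min_read = self.templated_len_range[0] + len(model.linker) + self.barcode_len
        if self.read_len < min_read:
            raise ValueError(
                f"read_len {self.read_len} too short to hold templated segment, "
                f"linker and barcode (needs >= {min_read})"
            )

    def resolved_end_distribution(self, model: ReferenceModel) -> dict[int, float]:
        if self.end_distribution is not None:
            return dict(self.end_distribution)
        return end_distribution_from_class_fractions(model, DEFAULT_CLASS_FRACTIONS)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["end_distribution"] is not None:
            d["end_distribution"] = {str(k): v for k, v in d["end_distribution"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if d.get("end_distribution") is not None:
            d["end_distribution"] = {int(k): float(v) for k, v in d["end_distribution"].items()}
        if "templated_len_range" in d:
            d["templated_len_range"] = tuple(d["templated_len_range"])
        return cls(**d)


def end_distribution_from_class_fractions(
    model: ReferenceModel, fractions: dict[str, float]
) -> dict[int, float]:
    """Spread class masses uniformly over each class's coordinate interval."""
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("class fractions must sum to 1")
    dist: dict[int, float] = {}
    for label, mass in fractions.items():
        lo, hi = model.class_bounds[label]
        span = hi - lo + 1
        for c in range(lo, hi + 1):
            dist[c] = dist.get(c, 0.0) + mass / span
    return dist


@dataclass
class TruthTable:
    """Ground truth of a simulated library.

    ``molecules``: one row per molecule (molecule_id, end_coord, tail,
    barcode, templated_len, n_copies). ``reads``: one row per emitted
    read (read_id, molecule_id).
    """

    molecules: pd.DataFrame
    reads: pd.DataFrame

    def write(self, prefix) -> None:
        self.molecules.to_csv(f"{prefix}.molecules.tsv", sep="\t", index=False)
        self.reads.to_csv(f"{prefix}.reads.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, prefix) -> "TruthTable":
        mols = pd.read_csv(f"{prefix}.molecules.tsv", sep="\t", keep_default_na=False)
        reads = pd.read_csv(f"{prefix}.reads.tsv", sep="\t")
        return cls(mols, reads)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode("ascii") if n > 0 else ""


def _apply_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0 or not seq:
        return seq
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(codes.size) < rate
    if hit.any():
        idx = np.nonzero(hit)[0]
        # replace with one of the three other bases
        cur = np.searchsorted(_BASES, codes[idx])
        offset = rng.integers(1, 4, size=idx.size)
        codes[idx] = _BASES[(cur + offset) % 4]
    return codes.tobytes().decode("ascii")


def build_read_sequence(
    model: ReferenceModel,
    end_coord: int,
    tail: str = "",
    templated_len: int = 60,
    barcode: str = "",
    linker_prefix_len: int | None = None,
    read_len: int | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """Deterministically lay out one read 5′→3′:

    [templated segment ending at ``end_coord``][tail][linker prefix]
    [barcode][random filler to ``read_len``], truncated to ``read_len``.

    With ``read_len=None`` no filler is added and nothing is truncated;
    useful for constructing exact sweep reads.
    """
    if templated_len > end_coord:
        templated_len = end_coord
    templated = model.sequence[end_coord - templated_len : end_coord]
    k = len(model.linker) if linker_prefix_len is None else linker_prefix_len
    read = templated + tail + model.linker[:k] + barcode
    if read_len is not None:
        if len(read) < read_len:
            if rng is None:
                rng = np.random.default_rng(0)
            read += _random_seq(rng, read_len - len(read))
        read = read[:read_len]
    return read


def simulate_library(
    model: ReferenceModel, config: SimulationConfig
) -> tuple[list, TruthTable]:
    """Generate the synthetic library; returns (reads, truth).

    Reads are :class:`~racemap.preprocess.ReadRecord` objects; output is
    bit-identical for identical (model, config) including the seed.
    """
    from .preprocess import ReadRecord

    config.validate(model)
    rng = np.random.default_rng(config.seed)
    dist = config.resolved_end_distribution(model)
    coords = np.array(sorted(dist), dtype=np.int64)
    probs = np.array([dist[c] for c in coords], dtype=float)
    probs = probs / probs.sum()

    n = config.n_molecules
    ends = rng.choice(coords, size=n, p=probs) if n else np.array([], dtype=np.int64)
    lo_t, hi_t = config.templated_len_range
    tlens = rng.integers(lo_t, hi_t + 1, size=n)
    has_tail = rng.random(n) < config.tail_prob
    tail_lens = np.where(
        has_tail, np.minimum(rng.geometric(1.0 / config.tail_mean, size=n), config.tail_cap), 0
    )
    copies = np.minimum(rng.geometric(1.0 / config.dup_mean, size=n), 50)

    mol_rows = []
    read_rows = []
    reads: list = []
    read_i = 0
    for m in range(n):
        end = int(ends[m])
        tlen = min(int(tlens[m]), end)
        tail_len = int(tail_lens[m])
        if tail_len and config.tail_non_a_rate > 0:
            tail = "".join(
                chr(rng.choice(_BASES[1:])) if rng.random() < config.tail_non_a_rate else "A"
                for _ in range(tail_len)
            )
        elif tail_len:
            tail = "A" * tail_len
        else:
            tail = ""
        barcode = _random_seq(rng, config.barcode_len)
        seq = build_read_sequence(
            model, end, tail=tail, templated_len=tlen, barcode=barcode,
            read_len=config.read_len, rng=rng,
        )
        if not config.post_copy_errors:
            seq = _apply_substitutions(seq, config.error_rate, rng)
        k = int(copies[m])
        mol_id = f"mol{m}"
        mol_rows.append((mol_id, end, tail, barcode, tlen, k))
        for _ in range(k):
            out = seq
            if config.post_copy_errors:
                out = _apply_substitutions(seq, config.error_rate, rng)
            rid = f"read{read_i}"
            reads.append(ReadRecord(id=rid, bases=out, qualities="I" * len(out)))
            read_rows.append((rid, mol_id))
            read_i += 1

    truth = TruthTable(
        molecules=pd.DataFrame(
            mol_rows,
            columns=["molecule_id", "end_coord", "tail", "barcode", "templated_len", "n_copies"],
        ),
        reads=pd.DataFrame(read_rows, columns=["read_id", "molecule_id"]),
    )
    return reads, truth


# -- FASTQ I/O ---------------------------------------------------------------


def _open_text(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_fastq(reads, path) -> None:
    """Write 4-line FASTQ (gzipped when the path ends in .gz)."""
    with _open_text(path, "w") as fh:
        for r in reads:
            qual = r.qualities or "I" * len(r.bases)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{qual}\n")


def read_fastq(path) -> list:
    """Read FASTQ into :class:`~racemap.preprocess.ReadRecord` objects."""
    from Bio import SeqIO
    from .preprocess import ReadRecord

    out = []
    with _open_text(path, "r") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            out.append(ReadRecord(id=rec.id, bases=str(rec.seq).upper(), qualities=qual))
    return out
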