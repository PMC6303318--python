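"""Reference model for single-transcript 3′-end mapping.

The model bundles everything the end-mapper and classifier need to know
about the transcript under study: the sense-strand sequence, the 1-based
coordinate frame (position 1 = transcription start), the window of
permitted 3′-end assignments, the constant 3′ linker ligated during
library preparation, and the labeled coordinate intervals that define the
3′-isoform classes.

Defaults describe human telomerase RNA (hTR): the mature form ends at
position 451, ends are assigned within 366–641, molecules ending at
452–460 are the 3′-extended short (exS) form and those ending beyond 460
the 3′-extended long (exL) form. Ends below 451 are reported as
``sub_mature``. The hTR sequence itself is never embedded; callers supply
it via FASTA (or use a synthetic sequence for testing).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

DEFAULT_MATURE_END = 451
DEFAULT_WINDOW_START = 366
DEFAULT_WINDOW_END = 641
DEFAULT_EXS_UPPER = 460
#: reporting sub-bins inside exS: the PARN-sensitive short ends and beyond
DEFAULT_SUB_BINS: tuple[tuple[int, int], ...] = ((452, 453), (454, 457), (458, 459))

_VALID = frozenset("ACGT")


class OutOfWindowError(ValueError):
    """A coordinate falls outside the model's end-assignment window."""


def _clean_sequence(seq: str, what: str) -> str:
    seq = str(seq).upper().replace("U", "T")
    if not seq or set(seq) - _VALID:
        bad = sorted(set(seq) - _VALID)
        raise ValueError(f"{what} contains non-ACGT characters: {bad!r}")
    return seq


@dataclass
class ReferenceModel:
    """Transcript reference plus coordinate conventions and isoform classes.

    Coordinates are 1-based and inclusive on the sense strand; an "end
    coordinate" is the position of the last templated base of a molecule.
    """

    sequence: str
    linker: str
    mature_end: int = DEFAULT_MATURE_END
    window_start: int = DEFAULT_WINDOW_START
    window_end: int = DEFAULT_WINDOW_END
    #: ordered {label: (lo, hi)} intervals jointly covering the window
    class_bounds: dict[str, tuple[int, int]] = field(default_factory=dict)
    #: optional finer reporting bins (label-free, coordinate pairs)
    sub_bins: tuple[tuple[int, int], ...] = DEFAULT_SUB_BINS

    def __post_init__(self) -> None:
        self.sequence = _clean_sequence(self.sequence, "reference sequence")
        self.linker = _clean_sequence(self.linker, "linker")
        if not self.class_bounds:
            self.class_bounds = default_class_bounds(
                self.window_start, self.window_end, self.mature_end
            )
        self.class_bounds = {k: (int(lo), int(hi)) for k, (lo, hi) in self.class_bounds.items()}
        self.sub_bins = tuple((int(lo), int(hi)) for lo, hi in self.sub_bins)
        self.validate()
        self._codes = np.frombuffer(self.sequence.encode("ascii"), dtype=np.uint8)
        self._windows: dict[int, np.ndarray] = {}

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if not (self.window_start <= self.mature_end <= self.window_end):
            raise ValueError(
                f"need window_start <= mature_end <= window_end, got "
                f"{self.window_start}, {self.mature_end}, {self.window_end}"
            )
        if self.window_start < 1:
            raise ValueError("window_start must be >= 1")
        if self.window_end > len(self.sequence):
            raise ValueError(
                f"reference ({len(self.sequence)} nt) shorter than "
                f"window_end ({self.window_end})"
            )
        # class intervals: ordered, disjoint, jointly cover the window
        cursor = self.window_start
        for label, (lo, hi) in self.class_bounds.items():
            if lo != cursor:
                raise ValueError(
                    f"class intervals must tile the window: expected {label!r} "
                    f"to start at {cursor}, got {lo}"
                )
            if hi < lo:
                raise ValueError(f"empty class interval {label!r}: [{lo}, {hi}]")
            cursor = hi + 1
        if cursor != self.window_end + 1:
            raise ValueError(
                f"class intervals end at {cursor - 1}, window ends at {self.window_end}"
            )

    # -- queries ------------------------------------------------------------

    @property
    def window(self) -> tuple[int, int]:
        return (self.window_start, self.window_end)

    @property
    def class_labels(self) -> tuple[str, ...]:
        return tuple(self.class_bounds)

    def classify(self, coord: int) -> str:
        """Class label of a templated 3′-end coordinate.

        Raises :class:`OutOfWindowError` for coordinates outside the
        assignment window; callers must never classify those silently.
        """
        coord = int(coord)
        if not (self.window_start <= coord <= self.window_end):
            raise OutOfWindowError(
                f"coordinate {coord} outside window "
                f"[{self.window_start}, {self.window_end}]"
            )
        for label, (lo, hi) in self.class_bounds.items():
            if lo <= coord <= hi:
                return label
        raise AssertionError("unreachable: intervals tile the window")

    def codes(self) -> np.ndarray:
        """Reference as uint8 ASCII codes (read-only view)."""
        return self._codes

    def anchor_windows(self, anchor_len: int) -> np.ndarray:
        """All length-``anchor_len`` reference windows, row i ending at
        1-based coordinate ``i + anchor_len``. Cached per anchor length."""
        if anchor_len not in self._windows:
            self._windows[anchor_len] = np.lib.stride_tricks.sliding_window_view(
                self._codes, anchor_len
            )
        return self._windows[anchor_len]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "sequence": self.sequence,
            "linker": self.linker,
            "mature_end": self.mature_end,
            "window_start": self.window_start,
            "window_end": self.window_end,
            "class_bounds": {k: list(v) for k, v in self.class_bounds.items()},
            "sub_bins": [list(b) for b in self.sub_bins],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceModel":
        return cls(
            sequence=d["sequence"],
            linker=d["linker"],
            mature_end=int(d.get("mature_end", DEFAULT_MATURE_END)),
            window_start=int(d.get("window_start", DEFAULT_WINDOW_START)),
            window_end=int(d.get("window_end", DEFAULT_WINDOW_END)),
            class_bounds={k: tuple(v) for k, v in d.get("class_bounds", {}).items()},
            sub_bins=tuple(tuple(b) for b in d.get("sub_bins", DEFAULT_SUB_BINS)),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ReferenceModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def with_overrides(self, **overrides) -> "ReferenceModel":
        return replace(self, **overrides)


def default_class_bounds(
    window_start: int, window_end: int, mature_end: int, exs_upper: int = DEFAULT_EXS_UPPER
) -> dict[str, tuple[int, int]]:
    """The four-way isoform scheme: sub_mature | mature | exS | exL."""
    return {
        "sub_mature": (window_start, mature_end - 1),
        "mature": (mature_end, mature_end),
        "exS": (mature_end + 1, exs_upper),
        "exL": (exs_upper + 1, window_end),
    }


def build_reference(sequence: str, linker: str, **overrides) -> ReferenceModel:
    """Build and validate a :class:`ReferenceModel` with defaults applied.

    ``overrides`` may set any model field (``mature_end``, ``window_start``,
    ``window_end``, ``class_bounds``, ``sub_bins``). Sequences are upcased
    and U is normalized to T; anything else non-ACGT is rejected.
    """
    return ReferenceModel(sequence=sequence, linker=linker, **overrides)


def classify_end(coord: int, model: ReferenceModel) -> str:
    """Functional spelling of :meth:`ReferenceModel.classify`."""
    return model.classify(coord)


def reference_from_fasta(path, linker: str, **overrides) -> ReferenceModel:
    """Build a model from a single-record FASTA file."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, found {len(records)}")
    return build_reference(str(records[0].seq), linker, **overrides)
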