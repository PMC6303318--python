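"""Anchored 3′-end assignment: examples, oracle equivalence, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from racemap import (
    SimulationConfig,
    assign_end,
    assign_ends,
    oracle_assign_end,
    simulate_library,
    tail_composition,
)
from racemap.endmap import ASSIGNED, NO_ANCHOR, OUT_OF_WINDOW, SHORT_MATCH, EndCall
from racemap.preprocess import process_reads


def mutate(seq: str, positions, rng=None) -> str:
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


# -- worked examples ---------------------------------------------------------


def test_exact_insert_assigned_without_tail(model):
    insert = model.sequence[431:451]  # ends at 451, no tail
    call = assign_end(insert, model)
    assert (call.status, call.end_coord, call.ntna, call.tail_trim) == (
        ASSIGNED, 451, "", 0,
    )
    assert call.anchor_mismatches == 0


def test_oligo_a_tail_called_as_ntna(model):
    """A pure-A tail is trimmed base by base until the anchor places; the
    base after 451 in this reference is not A, so nothing is absorbed.
    Verified against the exhaustive oracle."""
    assert model.sequence[451] != "A"
    insert = model.sequence[431:451] + "AAAAA"
    call = assign_end(insert, model)
    oracle = oracle_assign_end(insert, model)
    assert (call.status, call.end_coord, call.ntna) == (ASSIGNED, 451, "AAAAA")
    assert (oracle.status, oracle.end_coord, oracle.ntna) == (ASSIGNED, 451, "AAAAA")


def test_tail_absorption_when_reference_continues_with_a(model):
    """Tail bases matching the reference continuation are absorbed as
    templated: the assigned end is the most 3′ compatible coordinate."""
    # find an in-window coordinate whose next reference base is A
    coord = next(
        c for c in range(430, 451) if model.sequence[c] == "A" and model.sequence[c + 1] != "A"
    )
    insert = model.sequence[coord - 30 : coord] + "AAA"
    call = assign_end(insert, model)
    oracle = oracle_assign_end(insert, model)
    assert call.status == ASSIGNED
    assert call.end_coord == coord + 1  # one A absorbed
    assert call.ntna == "AA"
    assert (oracle.end_coord, oracle.ntna) == (call.end_coord, call.ntna)


def test_two_mismatches_tolerated_three_rejected(model):
    clean = model.sequence[411:451]  # 40 nt ending at 451
    # anchor body = positions len-20 .. len-3 (terminal two excluded)
    two = mutate(clean, [len(clean) - 5, len(clean) - 10])
    three = mutate(clean, [len(clean) - 5, len(clean) - 10, len(clean) - 15])
    call2 = assign_end(two, model)
    assert (call2.status, call2.end_coord, call2.anchor_mismatches) == (ASSIGNED, 451, 2)
    # with no trimming allowed there is no alternative placement at all
    call3 = assign_end(three, model, max_tail=0)
    assert call3.status == NO_ANCHOR
    assert oracle_assign_end(three, model, max_tail=0).status == NO_ANCHOR
    # trimming may still rescue the read at a shifted coordinate; whatever
    # happens, it matches the oracle
    assert assign_end(three, model) == oracle_assign_end(three, model)


def test_terminal_mismatch_forces_extra_trim(model):
    """A substitution in one of the two most-3′ bases cannot be accepted
    as a mismatch; the base is trimmed into the NTNA instead."""
    clean = model.sequence[411:451]
    bad_tip = mutate(clean, [len(clean) - 1])
    call = assign_end(bad_tip, model)
    oracle = oracle_assign_end(bad_tip, model)
    assert call == oracle
    assert call.status == ASSIGNED
    assert call.tail_trim >= 1


def test_terminal_free_mode_accepts_tip_mismatch(model):
    clean = model.sequence[411:451]
    bad_tip = mutate(clean, [len(clean) - 1])
    call = assign_end(bad_tip, model, terminal_free=True)
    assert (call.status, call.end_coord, call.tail_trim) == (ASSIGNED, 451, 0)


def test_short_inserts_rejected(model):
    assert assign_end(model.sequence[432:451], model).status == SHORT_MATCH  # 19 nt
    assert assign_end("", model).status == SHORT_MATCH
    assert oracle_assign_end("", model).status == SHORT_MATCH


def test_exact_window_insert(model):
    call = oracle_assign_end(model.sequence[431:451], model)
    assert (call.status, call.end_coord) == (ASSIGNED, 451)


def test_read_ending_beyond_window_is_out_of_window(model750):
    insert = model750.sequence[630:680]  # ends at 680 > 641
    call = assign_end(insert, model750)
    assert call.status == OUT_OF_WINDOW
    assert oracle_assign_end(insert, model750).status == OUT_OF_WINDOW


def test_non_nucleotide_insert_rejected(model):
    with pytest.raises(ValueError):
        assign_end("ACGTN" * 6, model)


def test_max_tail_cap(model):
    insert = model.sequence[431:451] + "AAAAA"
    capped = assign_end(insert, model, max_tail=3)
    assert capped.status == NO_ANCHOR
    assert assign_end(insert, model, max_tail=5).status == ASSIGNED


# -- oracle equivalence ------------------------------------------------------


def test_oracle_equivalence_on_simulated_library(model):
    """Vectorized and naive end assignment agree read-for-read on a
    seeded simulated library (errors, tails, duplicates included)."""
    cfg = SimulationConfig(n_molecules=400, error_rate=0.005, seed=41)
    reads, _ = simulate_library(model, cfg)
    with_linker, _ = process_reads(reads, model)
    for read in with_linker[:1000]:
        fast = assign_end(read.insert, model)
        slow = oracle_assign_end(read.insert, model)
        assert fast == slow, read.id


@settings(max_examples=120, deadline=None, derandomize=True)
@given(
    start=st.integers(min_value=340, max_value=660),
    length=st.integers(min_value=0, max_value=45),
    tail_len=st.integers(min_value=0, max_value=8),
    n_mut=st.integers(min_value=0, max_value=4),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_assign_matches_oracle_property(model, start, length, tail_len, n_mut, seed):
    """assign_end ≡ oracle_assign_end on randomized templated inserts with
    tails and substitutions."""
    end = min(start + length, len(model.sequence))
    rng = np.random.default_rng(seed)
    insert = model.sequence[start:end] + "A" * tail_len
    if insert and n_mut:
        positions = rng.integers(0, len(insert), size=min(n_mut, len(insert)))
        insert = mutate(insert, positions)
    assert assign_end(insert, model) == oracle_assign_end(insert, model)


# -- invariants --------------------------------------------------------------


def test_assigned_end_upper_bounds_true_end(model):
    """Without sequencing errors the assigned coordinate is >= the true
    end, with equality when the first tail base differs from the
    reference continuation."""
    cfg = SimulationConfig(n_molecules=300, error_rate=0.0, seed=43)
    reads, truth = simulate_library(model, cfg)
    with_linker, _ = process_reads(reads, model)
    mols = truth.molecules.set_index("molecule_id")
    mol_of = truth.reads.set_index("read_id")["molecule_id"]
    for read in with_linker:
        call = assign_end(read.insert, model)
        if call.status != ASSIGNED:
            continue
        true_end = int(mols.loc[mol_of[read.id], "end_coord"])
        tail = str(mols.loc[mol_of[read.id], "tail"])
        assert call.end_coord >= true_end
        if tail and model.sequence[true_end] != tail[0]:
            assert call.end_coord == true_end


def test_raising_max_mismatch_never_unassigns(model):
    rng = np.random.default_rng(45)
    inserts = []
    for _ in range(60):
        end = int(rng.integers(400, 640))
        seq = model.sequence[end - 40 : end]
        k = int(rng.integers(0, 4))
        seq = mutate(seq, rng.integers(0, 38, size=k))
        inserts.append(seq)
    for mm in (0, 1, 2):
        lo = {i for i, s in enumerate(inserts) if assign_end(s, model, max_mismatch=mm).status == ASSIGNED}
        hi = {i for i, s in enumerate(inserts) if assign_end(s, model, max_mismatch=mm + 1).status == ASSIGNED}
        assert lo <= hi


def test_minimal_trim_and_most_3prime_choice(model):
    """The chosen call uses the smallest trim with any valid placement and
    the most 3′ in-window coordinate at that trim (checked by direct
    enumeration)."""
    cfg = SimulationConfig(n_molecules=100, error_rate=0.002, seed=47)
    reads, _ = simulate_library(model, cfg)
    with_linker, _ = process_reads(reads, model)
    checked = 0
    for read in with_linker:
        call = assign_end(read.insert, model)
        if call.status != ASSIGNED:
            continue
        checked += 1
        # no smaller trim admits any placement
        for t in range(call.tail_trim):
            probe = oracle_assign_end(read.insert, model, max_tail=t)
            assert probe.status in (NO_ANCHOR, SHORT_MATCH)
    assert checked > 50


def test_assign_ends_marks_missing_linker(model):
    from racemap.preprocess import ReadRecord

    reads = [ReadRecord("a", "ACGT" * 20)]  # no insert populated
    calls = assign_ends(reads, model)
    assert calls[0].status == "no_linker"


# -- NTNA composition --------------------------------------------------------


@pytest.mark.parametrize(
    "ntna,expected,pure",
    [
        ("AAAAA", {"A": 5, "C": 0, "G": 0, "T": 0}, True),
        ("", {"A": 0, "C": 0, "G": 0, "T": 0}, False),
        ("AAT", {"A": 2, "C": 0, "G": 0, "T": 1}, False),
    ],
)
def test_tail_composition(ntna, expected, pure):
    call = EndCall("r", ASSIGNED, end_coord=451, ntna=ntna, tail_trim=len(ntna))
    counts, pure_a = tail_composition(call)
    assert counts == expected
    assert pure_a is pure


def test_tail_composition_requires_assignment():
    with pytest.raises(ValueError):
        tail_composition(EndCall("r", NO_ANCHOR))
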