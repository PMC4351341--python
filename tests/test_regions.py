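"""Hysteretic selection and the four-region partition vs. brute-force oracles."""

import numpy as np
import pytest

from adbfsim.core import minimum_image_distance
from adbfsim.regions import (BUFFER, CORE, DYN_QM, MM, RegionLabels, RegionSpec,
                             hysteretic_select, partition)

from conftest import random_state


# ---------------------------------------------------------------- oracles

def oracle_select(candidates, reference, prev, r_in, r_out, state, species_filter=None):
    """Literal set-comprehension re-implementation of the selection rule."""
    out = set()
    for a in candidates:
        if species_filter and state.species[a] not in species_filter:
            continue
        refs = [b for b in reference
                if not species_filter or state.species[b] in species_filter]
        if not refs:
            continue
        d = min(minimum_image_distance(state.positions[a], state.positions[b],
                                       state.cell, state.pbc) for b in refs)
        if d <= r_in or (a in prev and d <= r_out):
            out.add(a)
    return out


def oracle_partition(state, spec, prev):
    """Independent sequential-construction + molecule-promotion oracle."""
    n = state.n_atoms
    allset = set(range(n))
    prev_core = {i for i in range(n) if prev.label[i] <= CORE}
    prev_qm = {i for i in range(n) if prev.label[i] <= DYN_QM}
    prev_buf = {i for i in range(n) if prev.label[i] <= BUFFER}
    core = set(spec.fixed_core)
    if core and spec.r_core[1] > 0:
        core |= oracle_select(allset, set(spec.fixed_core), prev_core,
                              *spec.r_core, state, spec.species_filter)
    qm = set(core) | set(spec.fixed_qm)
    seed = set(spec.fixed_core) if spec.seed_is_only_fixed_core else set(core)
    if seed and spec.r_qm[1] > 0:
        qm |= oracle_select(allset, seed, prev_qm, *spec.r_qm, state, spec.species_filter)
    buf = set(spec.fixed_buffer)
    if qm and spec.r_buffer[1] > 0:
        buf |= oracle_select(allset, qm, prev_buf, *spec.r_buffer, state,
                             spec.species_filter)
    label = np.full(n, MM, dtype=np.int8)
    for i in buf:
        label[i] = BUFFER
    for i in qm:
        label[i] = DYN_QM
    for i in core:
        label[i] = CORE
    if spec.whole_molecules:
        for m in np.unique(state.molecule_id):
            atoms = np.flatnonzero(state.molecule_id == m)
            label[atoms] = label[atoms].min()
    return label


def random_prev(rng, n):
    return RegionLabels(rng.integers(0, 4, n).astype(np.int8))


# ------------------------------------------------------------------ tests

class TestHystereticSelect:
    def test_degenerate_equals_plain_cutoff(self, medium_box):
        rng = np.random.default_rng(0)
        n = medium_box.n_atoms
        ref = [0, 1, 2]
        for _ in range(5):
            prev = set(rng.choice(n, 10, replace=False).tolist())
            with_prev = hysteretic_select(range(n), ref, prev, 3.0, 3.0, medium_box)
            without = hysteretic_select(range(n), ref, set(), 3.0, 3.0, medium_box)
            assert np.array_equal(with_prev, without)

    def test_hysteretic_band_membership_depends_on_history(self):
        """An atom between r_in and r_out stays only if already a member."""
        from conftest import random_state
        rng = np.random.default_rng(1)
        state = random_state(rng, n_molecules=2, edge=30.0)
        state.positions[:] = 0.0
        state.positions[3] = [4.2, 0.0, 0.0]  # inside the 4.0-4.5 band
        sel_in = hysteretic_select([3], [0], {3}, 4.0, 4.5, state)
        sel_out = hysteretic_select([3], [0], set(), 4.0, 4.5, state)
        assert 3 in sel_in and 3 not in sel_out

    def test_invalid_radii_and_empty_reference(self, small_box):
        with pytest.raises(ValueError):
            hysteretic_select([0], [1], set(), 2.0, 1.0, small_box)
        with pytest.raises(ValueError):
            hysteretic_select([0], [], set(), 1.0, 2.0, small_box)

    def test_matches_set_comprehension_oracle(self):
        rng = np.random.default_rng(42)
        for trial in range(20):
            state = random_state(rng, n_molecules=6, edge=9.0)
            n = state.n_atoms
            ref = rng.choice(n, 3, replace=False).tolist()
            prev = set(rng.choice(n, 8, replace=False).tolist())
            r_in = rng.uniform(1.0, 4.0)
            r_out = r_in + rng.uniform(0.0, 1.5)
            filt = ("O", "O") if trial % 2 else None
            got = set(hysteretic_select(range(n), ref, prev, r_in, r_out, state, filt).tolist())
            assert got == oracle_select(range(n), ref, prev, r_in, r_out, state, filt)


class TestPartition:
    def test_all_radii_zero_is_conventional(self, medium_box):
        spec = RegionSpec(fixed_core=(0, 1, 2))
        lab = partition(medium_box, spec, RegionLabels.initial(medium_box.n_atoms, spec))
        assert set(lab.core.tolist()) == {0, 1, 2}
        assert set(lab.dyn_qm.tolist()) == {0, 1, 2}
        assert len(lab.buffer) == 0

    def test_adconv_configuration_core_equals_dyn_qm(self, medium_box):
        spec = RegionSpec(fixed_core=(0, 1, 2), r_core=(2.5, 3.0))
        lab = partition(medium_box, spec, RegionLabels.initial(medium_box.n_atoms, spec))
        assert np.array_equal(lab.core, lab.dyn_qm)
        assert len(lab.buffer) == 0

    def test_matches_brute_force_oracle_randomized(self):
        """Nesting, idempotence and oracle agreement on random configs."""
        rng = np.random.default_rng(7)
        for trial in range(60):
            state = random_state(rng, n_molecules=7, edge=10.0)
            spec = RegionSpec(
                fixed_core=(0, 1, 2),
                r_core=(0.0, 0.0) if trial % 3 == 0 else (2.0, 2.5),
                r_qm=(3.0, 3.5), r_buffer=(2.5, 3.0) if trial % 2 else (0.0, 0.0),
                species_filter=("O", "O") if trial % 4 == 0 else None,
                whole_molecules=bool(trial % 2),
            )
            prev = random_prev(rng, state.n_atoms)
            lab = partition(state, spec, prev)
            assert np.array_equal(lab.label, oracle_partition(state, spec, prev))
            # nesting and disjointness
            assert set(lab.core) <= set(lab.dyn_qm)
            assert not (set(lab.dyn_qm) & set(lab.buffer))
            # idempotence w.r.t. the same prev
            again = partition(state, spec, prev)
            assert np.array_equal(lab.label, again.label)

    def test_monotonicity_in_inner_radius(self):
        rng = np.random.default_rng(19)
        state = random_state(rng, n_molecules=8, edge=10.0)
        prev = RegionLabels.initial(state.n_atoms)
        sizes = []
        for r_in in (1.0, 2.0, 3.0, 4.0):
            spec = RegionSpec(fixed_core=(0, 1, 2), r_qm=(r_in, 4.5))
            sizes.append(len(partition(state, spec, prev).dyn_qm))
        assert sizes == sorted(sizes)

    def test_fixed_buffer_atom_promoted_into_qm(self):
        rng = np.random.default_rng(3)
        state = random_state(rng, n_molecules=3, edge=25.0)
        state.positions[:] = rng.uniform(0, 25, (9, 3))
        state.positions[3] = state.positions[0] + [1.0, 0, 0]  # well inside r_qm
        spec = RegionSpec(fixed_core=(0,), fixed_buffer=(3,), r_qm=(2.0, 2.5),
                          whole_molecules=False)
        lab = partition(state, spec, RegionLabels.initial(9, spec))
        assert lab.label[3] == DYN_QM  # inner selection wins over outer fixed list

    def test_max_extended_cap(self, medium_box):
        spec = RegionSpec(fixed_core=(0, 1, 2), r_qm=(4.0, 4.5), r_buffer=(4.0, 4.5),
                          max_extended_atoms=5)
        with pytest.raises(RuntimeError, match="max_extended_atoms"):
            partition(medium_box, spec, RegionLabels.initial(medium_box.n_atoms, spec))

    def test_fixed_lists_must_be_disjoint(self):
        with pytest.raises(ValueError):
            RegionSpec(fixed_core=(0,), fixed_qm=(0,))
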