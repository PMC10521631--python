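"""Mobility conversion, 2σ aggregation (against a brute-force oracle),
deduplication and dataset alignment."""

import numpy as np
import pytest

from ccspred import chem, preprocess
from ccspred import synthetic_data as synth
from ccspred.io_formats import Dataset, IonRecord
from ccspred.preprocess import (
    MobilityConstants,
    aggregate_group,
    align_datasets,
    ccs_to_k0,
    deduplicate,
    k0_to_ccs,
)


class TestMasonSchamp:
    def test_linear_in_inv_k0(self):
        a = k0_to_ccs(0.55, 2, 1500.0)
        b = k0_to_ccs(1.10, 2, 1500.0)
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_roundtrip_inverse(self):
        x = 400.0
        assert k0_to_ccs(ccs_to_k0(x, 2, 1200.0), 2, 1200.0) == pytest.approx(x, rel=1e-9)

    def test_frozen_regression_value(self):
        # independent constant-by-constant hand evaluation of the reduced-mass
        # kinetic-theory formula (N2 gas, 305 K), frozen once
        assert k0_to_ccs(
            1.10, 2, 1500.0, MobilityConstants(gas_mass=28.013, temperature=305.0)
        ) == pytest.approx(444.645571, abs=1e-4)

    def test_monotone_in_inv_k0_and_charge(self):
        grid = np.linspace(0.6, 1.6, 11)
        vals = [k0_to_ccs(v, 2, 1500.0) for v in grid]
        assert all(a < b for a, b in zip(vals, vals[1:]))
        assert k0_to_ccs(1.0, 3, 1500.0) > k0_to_ccs(1.0, 2, 1500.0)

    @pytest.mark.parametrize("bad", [(0.0, 2, 1500.0), (1.0, 0, 1500.0), (1.0, 2, -5.0)])
    def test_rejects_nonpositive(self, bad):
        with pytest.raises(ValueError):
            k0_to_ccs(*bad)


def brute_force_aggregate(group):
    """Independent occurrence-expansion implementation of the 2σ fusion rule."""
    expanded = [c for c, o in group for _ in range(o)]
    sigma = float(np.std(expanded))  # population std over expanded values
    cutoff = 2 * sigma * (1 + 1e-12) + 1e-12  # float guard on the boundary

    def fuse(instances):
        main = sorted(instances, key=lambda t: (-t[1], t[0]))[0]
        members = [t for t in instances if abs(t[0] - main[0]) <= cutoff]
        vals = [c for c, o in members for _ in range(o)]
        rest = [t for t in instances if abs(t[0] - main[0]) > cutoff]
        return rest, float(np.mean(vals)), sum(o for _, o in members)

    remaining = list(group)
    remaining, ccs, occ = fuse(remaining)
    n_modes, dropped = 1, 0
    while remaining:
        remaining, _, mode_occ = fuse(remaining)
        n_modes += 1
        dropped += mode_occ
    return ccs, occ, n_modes, dropped


class TestAggregateGroup:
    def test_worked_example(self):
        ccs, occ, modality, n_modes, dropped = aggregate_group([(500, 4), (501, 4), (530, 2)])
        assert ccs == pytest.approx(500.5)
        assert occ == 8
        assert modality == "multimodal"
        assert n_modes == 2
        assert dropped == 2

    def test_singleton(self):
        assert aggregate_group([(400, 7)]) == (400.0, 7, "unimodal", 1, 0)

    def test_close_pair_fused(self):
        ccs, occ, modality, n_modes, _ = aggregate_group([(600, 1), (600.5, 1)])
        assert ccs == pytest.approx(600.25)
        assert occ == 2 and modality == "unimodal" and n_modes == 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            aggregate_group([])

    def test_matches_brute_force_oracle_on_random_groups(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            k = int(rng.integers(1, 6))
            ccs_vals = np.round(rng.uniform(300, 700, size=k), 2)
            # distinct instances (duplicate ccs values merge upstream)
            ccs_vals = np.unique(ccs_vals)
            group = [(float(c), int(rng.integers(1, 8))) for c in ccs_vals]
            got = aggregate_group(group)
            want = brute_force_aggregate(group)
            assert got[0] == pytest.approx(want[0], rel=1e-12)
            assert (got[1], got[3], got[4]) == (want[1], want[2], want[3])


def make_ds(rows):
    return Dataset(
        records=[
            IonRecord(sequence=chem.tokenize(s), charge=z, mz=m, ccs=c, occurrence=o)
            for s, z, m, c, o in rows
        ]
    )


class TestDeduplicate:
    def test_no_duplicates_identity(self):
        ds = make_ds([("AAK", 2, 150.0, 380.0, 1), ("PEK", 2, 180.0, 390.0, 1)])
        out = deduplicate(ds)
        assert len(out) == 2
        assert all(r.occurrence == 1 and r.n_modes == 1 for r in out.records)

    def test_exact_duplicates_merge(self):
        ds = make_ds([("AAK", 2, 150.0, 380.0, 1), ("AAK", 2, 150.0, 380.0, 1)])
        out = deduplicate(ds)
        assert len(out) == 1
        rec = out.records[0]
        assert rec.occurrence == 2 and rec.ccs == pytest.approx(380.0)
        assert rec.modality == "unimodal"

    def test_occurrence_conservation_and_key_multiset(self):
        truth = synth.SyntheticTruth(seed=3, multimodal_fraction=0.1)
        ds, _ = synth.generate(truth, 400)
        out = deduplicate(ds)
        total_in = sum(r.occurrence for r in ds.records)
        total_out = sum(r.occurrence + r.dropped_occurrence for r in out.records)
        assert total_in == total_out
        assert {(r.sequence, r.charge) for r in ds.records} == {
            (r.sequence, r.charge) for r in out.records
        }

    def test_injected_bimodal_fraction_recovered(self):
        truth = synth.SyntheticTruth(seed=9, multimodal_fraction=0.05, mode_separation=30.0)
        ds, components = synth.generate(truth, 2000)
        injected = set(components.attrs["injected_keys"])
        out = deduplicate(ds)
        flagged = {
            (r.sequence, r.charge) for r in out.records if r.modality == "multimodal"
        }
        recall = len(flagged & injected) / len(injected)
        false_pos = len(flagged - injected) / max(1, len(out) - len(injected))
        assert recall >= 0.9
        assert false_pos <= 0.01


class TestAlign:
    def test_identity_alignment(self):
        ds = make_ds([("AAK", 2, 150.0, 380.0, 1), ("PEK", 3, 180.0, 420.0, 1)])
        shift, shifted = align_datasets(ds, ds)
        assert shift.shift == pytest.approx(0.0, abs=1e-12)
        assert shift.n_matched == 2

    def test_constant_offset_recovered_exactly(self):
        ref = make_ds([("AAK", 2, 150.0, 380.0, 1), ("PEK", 3, 180.0, 420.0, 1)])
        tgt = make_ds([("AAK", 2, 150.0, 375.0, 1), ("PEK", 3, 180.0, 415.0, 1)])
        shift, shifted = align_datasets(tgt, ref)
        assert shift.shift == pytest.approx(5.0, abs=1e-12)
        diffs = [a.ccs - b.ccs for a, b in zip(ref.records, shifted.records)]
        assert np.mean(diffs) == pytest.approx(0.0, abs=1e-9)

    def test_alignment_idempotent(self):
        ref = make_ds([("AAK", 2, 150.0, 380.0, 1), ("PEK", 3, 180.0, 420.0, 1)])
        tgt = make_ds([("AAK", 2, 150.0, 375.0, 1), ("PEK", 3, 180.0, 415.0, 1)])
        _, shifted = align_datasets(tgt, ref)
        shift2, _ = align_datasets(shifted, ref)
        assert shift2.shift == pytest.approx(0.0, abs=1e-9)

    def test_disjoint_keys_error(self):
        a = make_ds([("AAK", 2, 150.0, 380.0, 1)])
        b = make_ds([("PEK", 3, 180.0, 420.0, 1)])
        with pytest.raises(ValueError):
            align_datasets(a, b)

    def test_shift_tracked_in_metadata(self):
        ref = make_ds([("AAK", 2, 150.0, 380.0, 1)])
        tgt = make_ds([("AAK", 2, 150.0, 370.0, 1)])
        shift, shifted = align_datasets(tgt, ref)
        assert shifted.alignment_shift == pytest.approx(10.0)
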