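"""Diagnostic sites, tract calling, mosaic tables and dispersion."""

import random

import numpy as np
import pandas as pd
import pytest

import karyorec as kr
from karyorec.genotyping import ALT, MISSING, NONE, REF, STRONG, GenotypeMatrix
from karyorec.io import Reference, SiteObservation
from karyorec.recombination import (
    call_tracts,
    dispersion,
    find_diagnostic_sites,
    genotype_table,
)
from tests.conftest import run_pipeline


def make_matrix(calls, positions=None, support=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    positions = positions if positions is not None else np.arange(1, m + 1) * 100
    sites = pd.DataFrame(
        {
            "scaffold": ["s1"] * m,
            "pos": positions,
            "ref": ["A"] * m,
            "alt": ["C"] * m,
        }
    )
    if support is None:
        support = np.where(calls != MISSING, STRONG, NONE).astype(np.int8)
    return GenotypeMatrix([f"n{i}" for i in range(n)], sites, calls, support)


CLADES6 = {f"n{i}": 1 if i < 3 else 2 for i in range(6)}


class TestDiagnosticSites:
    def test_opposed_consensuses_are_diagnostic(self):
        m = make_matrix([[REF]] * 3 + [[ALT]] * 3)
        diag = find_diagnostic_sites(m, CLADES6)
        assert len(diag) == 1
        d = diag[0]
        assert (d.clade1_call, d.clade2_call) == (REF, ALT)
        assert d.n_votes_clade1 == 3 and d.n_votes_clade2 == 3

    def test_split_clade_has_no_consensus(self):
        clades = {f"n{i}": 1 if i < 4 else 2 for i in range(7)}
        calls = [[REF], [REF], [ALT], [ALT], [ALT], [ALT], [ALT]]
        assert find_diagnostic_sites(make_matrix(calls), clades) == []

    def test_agreeing_clades_not_diagnostic(self):
        m = make_matrix([[ALT]] * 6)
        assert find_diagnostic_sites(m, CLADES6) == []

    def test_min_votes_enforced(self):
        calls = [[REF], [MISSING], [MISSING], [ALT], [ALT], [ALT]]
        assert find_diagnostic_sites(make_matrix(calls), CLADES6, min_votes=2) == []

    def test_empty_clade_rejected(self):
        m = make_matrix([[REF]] * 3)
        with pytest.raises(ValueError):
            find_diagnostic_sites(m, {"n0": 1, "n1": 1, "n2": 1})


CLADES8 = {f"n{i}": 1 if i < 5 else 2 for i in range(8)}


def mosaic_matrix(row0):
    """8-nucleus matrix; nucleus n0 (clade 1) gets the given call row, the
    other four clade-1 nuclei are all-REF and the three clade-2 nuclei are
    all-ALT (so columns where n0 deviates keep >= 80% clade-1 agreement)."""
    m = len(row0)
    calls = [row0] + [[REF] * m] * 4 + [[ALT] * m] * 3
    return make_matrix(calls)


class TestCallTracts:
    def test_three_consecutive_opposite_sites_make_one_tract(self):
        m = mosaic_matrix([REF, ALT, ALT, ALT, REF])
        diag = find_diagnostic_sites(m, CLADES8)
        tracts = call_tracts(m, diag, CLADES8)
        assert len(tracts) == 1
        t = tracts[0]
        assert (t.nucleus, t.n_supporting) == ("n0", 3)
        assert (t.start, t.end) == (200, 400)
        assert (t.own_clade, t.donor_clade) == (1, 2)
        assert (t.outer_start, t.outer_end) == (100, 500)

    def test_single_isolated_opposite_site_is_not_a_tract(self):
        m = mosaic_matrix([REF, ALT, REF])
        diag = find_diagnostic_sites(m, CLADES8)
        assert call_tracts(m, diag, CLADES8, min_run=2) == []

    def test_missing_sites_neither_break_nor_extend(self):
        m = mosaic_matrix([REF, ALT, MISSING, ALT, REF])
        diag = find_diagnostic_sites(m, CLADES8)
        tracts = call_tracts(m, diag, CLADES8)
        assert len(tracts) == 1 and tracts[0].n_supporting == 2
        assert (tracts[0].start, tracts[0].end) == (200, 400)

    def test_order_invariance(self):
        m = mosaic_matrix([REF, ALT, ALT, REF, ALT, ALT])
        diag = find_diagnostic_sites(m, CLADES8)
        shuffled = diag[:]
        random.Random(3).shuffle(shuffled)
        assert call_tracts(m, diag, CLADES8) == call_tracts(m, shuffled, CLADES8)

    def test_unlabelled_nucleus_skipped_with_warning(self):
        m = mosaic_matrix([REF, ALT, ALT])
        diag = find_diagnostic_sites(m, CLADES8)
        clades = dict(CLADES8)
        clades.pop("n0")
        with pytest.warns(UserWarning, match="no clade label"):
            assert call_tracts(m, diag, clades) == []


class TestGenotypeTable:
    def test_rows_and_missing_cells(self):
        m = mosaic_matrix([REF, ALT, ALT, MISSING])
        diag = find_diagnostic_sites(m, CLADES8)
        table = genotype_table(m, diag, CLADES8, "s1")
        row_n0 = table.loc["n0 (clade1)"]
        assert list(row_n0) == ["clade1", "clade2", "clade2", ""]
        assert (table.loc["n5 (clade2)"] == "clade2").all()

    def test_opposite_block_matches_called_tract(self):
        m = mosaic_matrix([REF, ALT, ALT, ALT, REF])
        diag = find_diagnostic_sites(m, CLADES8)
        tract = call_tracts(m, diag, CLADES8)[0]
        table = genotype_table(m, diag, CLADES8, "s1")
        opp_cols = [
            pos for pos in table.columns if table.loc["n0 (clade1)", pos] == "clade2"
        ]
        assert (min(opp_cols), max(opp_cols)) == (tract.start, tract.end)


class TestSimulatedTracts:
    def _planted_run(self, seed, with_tracts):
        cfg0 = kr.SimConfig(seed=seed, error_rate=0.001)
        base = kr.simulate(cfg0)
        nucleus = cfg0.nucleus_names[2]
        tract = None
        for scaffold, mask in base.truth.masks[nucleus].items():
            pos = base.truth.snp_pos[scaffold]
            for s, e in mask:
                inside = pos[(pos >= s) & (pos <= e)]
                if len(inside) >= 8:
                    tract = (2, scaffold, int(inside[0]) - 10, int(inside[7]) + 10)
                    break
            if tract:
                break
        assert tract is not None, "no covered block with enough truth SNPs"
        tracts = [tract] if with_tracts else []
        cfg = kr.SimConfig(seed=seed, recomb_tracts=tracts, error_rate=0.001)
        return run_pipeline(cfg), tracts

    def test_planted_tract_recovered_and_twin_contrast(self):
        run, planted = self._planted_run(33, with_tracts=True)
        twin, _ = self._planted_run(33, with_tracts=False)
        diag = find_diagnostic_sites(run.matrix, run.similarity.clades)
        tracts = call_tracts(run.matrix, diag, run.similarity.clades)
        diag_twin = find_diagnostic_sites(twin.matrix, twin.similarity.clades)
        tracts_twin = call_tracts(twin.matrix, diag_twin, twin.similarity.clades)
        _, scaffold, start, end = planted[0]
        nucleus = run.cfg.nucleus_names[2]
        hits = [
            t
            for t in tracts
            if t.nucleus == nucleus and t.scaffold == scaffold
            and start <= t.start <= t.end <= end
        ]
        carrier_diag = [
            d for d in diag
            if d.scaffold == scaffold and start <= d.pos <= end
            and run.matrix.calls[run.matrix.nucleus_index(nucleus), d.site_index]
            != MISSING
        ]
        if len(carrier_diag) >= 2:
            assert len(hits) == 1
        assert len(tracts) > len(tracts_twin)

    def test_false_tract_rate_low_under_error(self):
        run = run_pipeline(kr.SimConfig(seed=44, error_rate=0.005))
        diag = find_diagnostic_sites(run.matrix, run.similarity.clades)
        tracts = call_tracts(run.matrix, diag, run.similarity.clades, min_run=2)
        n_nuclei = len(run.matrix.nuclei)
        rate = len(tracts) / n_nuclei / max(len(diag) / 100, 1e-9)
        assert rate < 0.05


class TestDispersion:
    def setup_method(self):
        self.ref = Reference({"s1": "A" * 1000, "s2": "C" * 400})

    def test_percent_normalization(self):
        obs = [
            SiteObservation("s1", 500, "A", "C", 0, 5),
            SiteObservation("s1", 1000, "A", "C", 0, 5),
        ]
        df = dispersion(obs, self.ref)
        assert list(df["percent_of_scaffold"]) == [50.0, 100.0]

    def test_long_variants_excluded(self):
        obs = [SiteObservation("s1", 10, "A", "AT", 0, 5)]
        assert dispersion(obs, self.ref).empty

    def test_scaffold_one_only_flag(self):
        obs = [
            SiteObservation("s1", 10, "A", "C", 0, 5),
            SiteObservation("s2", 10, "C", "G", 0, 5),
        ]
        df = dispersion(obs, self.ref, scaffold_one_only=True)
        assert set(df["scaffold"]) == {"s1"}
        assert df.attrs["plot_alpha"] == 0.2

    def test_position_beyond_scaffold_rejected(self):
        obs = [SiteObservation("s1", 1001, "A", "C", 0, 5)]
        with pytest.raises(ValueError):
            dispersion(obs, self.ref)
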