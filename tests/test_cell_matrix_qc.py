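"""Matrix and QC contracts: exact UMI collapse, boundary semantics of the
three exclusion rules, and the passenger-free flag."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from passenger_tracer import (
    QCThresholds,
    ReporterHit,
    build_matrix,
    flag_passenger_free,
    qc_filter,
)
from passenger_tracer.cell_matrix_qc import CountMatrix


def _calls(rows):
    return pd.DataFrame(rows, columns=["read_id", "barcode", "umi", "label", "best_gene"])


class TestBuildMatrix:
    def test_same_triple_collapses_to_one(self):
        calls = _calls(
            [("r0", "B1", "U1", "mouse", "g1"), ("r1", "B1", "U1", "mouse", "g1")]
        )
        m = build_matrix(calls, ["B1"])
        assert m.counts.toarray().tolist() == [[1]]

    def test_distinct_umis_count_separately(self):
        calls = _calls(
            [("r0", "B1", "U1", "mouse", "g1"), ("r1", "B1", "U2", "mouse", "g1")]
        )
        m = build_matrix(calls, ["B1"])
        assert m.counts.toarray().tolist() == [[2]]

    def test_only_whitelisted_mouse_reads_contribute(self):
        calls = _calls(
            [
                ("r0", "B1", "U1", "mouse", "g1"),
                ("r1", "B1", "U2", "human", "hg1"),
                ("r2", "B1", "U3", "ambiguous", ""),
                ("r3", "B1", "U4", "unaligned", ""),
                ("r4", "B9", "U5", "mouse", "g1"),  # not whitelisted
            ]
        )
        m = build_matrix(calls, ["B1"])
        assert m.barcodes == ("B1",)
        assert m.gene_ids == ("g1",)
        assert m.counts.sum() == 1

    def test_random_fixture_matches_triple_set_oracle(self):
        """Matrix total equals the number of distinct (barcode, UMI, gene)
        triples among contributing reads, counted by brute force."""
        rng = np.random.default_rng(47)
        barcodes = [f"B{i:02d}" for i in range(12)]
        genes = [f"g{i}" for i in range(9)]
        rows = []
        for i in range(300):
            rows.append(
                (
                    f"r{i}",
                    barcodes[rng.integers(0, 12)],
                    f"U{rng.integers(0, 5)}",
                    ["mouse", "human", "unaligned"][rng.integers(0, 3)],
                    genes[rng.integers(0, 9)],
                )
            )
        calls = _calls(rows)
        wl = barcodes[:10]
        m = build_matrix(calls, wl)
        oracle = {
            (b, u, g)
            for _, b, u, lab, g in rows
            if lab == "mouse" and b in wl
        }
        assert m.counts.sum() == len(oracle)
        # spot-check one entry
        b, g = sorted({(t[0], t[2]) for t in oracle})[0]
        expected = len({t[1] for t in oracle if t[0] == b and t[2] == g})
        bi, gi = m.barcodes.index(b), m.gene_ids.index(g)
        assert m.counts[bi, gi] == expected


def _matrix_from_rows(row_specs, n_genes=700, n_mito=10):
    """row_specs: list of dicts with n_genes, n_umis, mito_umis."""
    genes = tuple(
        [f"mt-g{i:03d}" for i in range(n_mito)]
        + [f"g{i:03d}" for i in range(n_genes - n_mito)]
    )
    barcodes = tuple(f"B{i:03d}" for i in range(len(row_specs)))
    mat = sp.lil_matrix((len(row_specs), n_genes), dtype=np.int64)
    for r, spec in enumerate(row_specs):
        ng, nu, mu = spec["n_genes"], spec["n_umis"], spec["mito_umis"]
        assert ng <= n_genes and mu <= nu
        # mito UMIs on the first mito gene; remaining genes get 1 UMI each,
        # with the surplus piled on the first non-mito gene
        cols = []
        if mu > 0:
            cols.append((0, mu))
        n_plain = ng - (1 if mu > 0 else 0)
        surplus = nu - mu - n_plain
        for j in range(n_plain):
            cols.append((n_mito + j, 1 + (surplus if j == 0 else 0)))
        for c, v in cols:
            mat[r, c] = v
    m = CountMatrix(barcodes=barcodes, gene_ids=genes, counts=mat.tocsr())
    mito_ids = [g for g in genes if g.startswith("mt-")]
    return m, mito_ids


class TestQCFilter:
    def test_boundary_gene_count_excluded(self):
        """499 detected genes is excluded under 'fewer than 500'."""
        m, mito = _matrix_from_rows(
            [
                {"n_genes": 499, "n_umis": 700, "mito_umis": 7},
                {"n_genes": 500, "n_umis": 700, "mito_umis": 7},
            ]
        )
        profiles, wl = qc_filter(m, mito, QCThresholds())
        assert profiles["passed_qc"].tolist() == [False, True]
        assert profiles["fail_min_genes"].tolist() == [True, False]
        assert wl == ["B001"]

    def test_boundary_mito_fraction_excluded(self):
        """91/900 = 10.11% mitochondrial UMIs is excluded (> 10% exactly)."""
        m, mito = _matrix_from_rows(
            [
                {"n_genes": 600, "n_umis": 900, "mito_umis": 91},
                {"n_genes": 600, "n_umis": 900, "mito_umis": 90},  # exactly 10%
            ]
        )
        profiles, wl = qc_filter(m, mito, QCThresholds())
        assert profiles["fail_mito"].tolist() == [True, False]
        assert profiles["passed_qc"].tolist() == [False, True]

    def test_low_novelty_excluded(self):
        # log10(550)/log10(5000) = 0.741 < 0.8
        m, mito = _matrix_from_rows([{"n_genes": 550, "n_umis": 5000, "mito_umis": 0}])
        profiles, wl = qc_filter(m, mito, QCThresholds())
        assert profiles["novelty"].iloc[0] == pytest.approx(
            np.log10(550) / np.log10(5000)
        )
        assert not profiles["passed_qc"].iloc[0]
        assert profiles["fail_complexity"].iloc[0]

    def test_single_umi_cell_fails(self):
        m, mito = _matrix_from_rows([{"n_genes": 1, "n_umis": 1, "mito_umis": 0}])
        profiles, wl = qc_filter(m, mito, QCThresholds(min_genes=1))
        assert np.isnan(profiles["novelty"].iloc[0])
        assert not profiles["passed_qc"].iloc[0]

    def test_literal_umi_ratio_reading_excludes_nothing(self):
        """The literal 'UMIs per gene below 0.8' rule is vacuous: every
        detected gene has >= 1 UMI, so the ratio is always >= 1."""
        specs = [
            {"n_genes": 499, "n_umis": 700, "mito_umis": 7},
            {"n_genes": 550, "n_umis": 5000, "mito_umis": 0},
            {"n_genes": 600, "n_umis": 900, "mito_umis": 0},
        ]
        m, mito = _matrix_from_rows(specs)
        thr = QCThresholds(min_genes=1, max_mito=1.0, literal_umi_ratio=True)
        profiles, wl = qc_filter(m, mito, thr)
        assert profiles["passed_qc"].all()
        assert (profiles["umi_per_gene"] >= 1.0).all()

    def test_cohort_matches_brute_force_predicates(self):
        """Planted cohort incl. boundary cells: pass/fail equals direct
        evaluation of the three predicates."""
        rng = np.random.default_rng(53)
        specs = [
            {"n_genes": 499, "n_umis": 700, "mito_umis": 7},
            {"n_genes": 600, "n_umis": 900, "mito_umis": 91},
            {"n_genes": 550, "n_umis": 5000, "mito_umis": 0},
            {"n_genes": 520, "n_umis": 800, "mito_umis": 80},
        ]
        for _ in range(30):
            ng = int(rng.integers(400, 600))
            mu = int(rng.integers(0, 120))
            nu = int(rng.integers(ng + mu, 3 * ng))
            specs.append({"n_genes": ng, "n_umis": nu, "mito_umis": mu})
        m, mito = _matrix_from_rows(specs)
        profiles, wl = qc_filter(m, mito, QCThresholds())
        for spec, (_, row) in zip(specs, profiles.iterrows()):
            ng, nu, mu = spec["n_genes"], spec["n_umis"], spec["mito_umis"]
            expected = (
                ng >= 500
                and nu >= 2
                and np.log10(ng) / np.log10(nu) >= 0.8
                and mu / nu <= 0.10
            )
            assert row["passed_qc"] == expected, spec

    def test_raising_min_genes_never_admits_a_cell(self):
        rng = np.random.default_rng(59)
        specs = [
            {
                "n_genes": int(rng.integers(2, 600)),
                "n_umis": 0,
                "mito_umis": int(rng.integers(0, 5)),
            }
            for _ in range(25)
        ]
        for s in specs:
            s["n_umis"] = int(rng.integers(s["n_genes"] + s["mito_umis"], 4 * s["n_genes"] + 10))
        m, mito = _matrix_from_rows(specs)
        prev = None
        for min_genes in (1, 100, 300, 500):
            profiles, _ = qc_filter(
                m, mito, QCThresholds(min_genes=min_genes, novelty_min=0.0, max_mito=1.0)
            )
            passed = set(profiles.loc[profiles["passed_qc"], "barcode"])
            if prev is not None:
                assert passed <= prev
            prev = passed


class TestFlagPassengerFree:
    def _profiles(self, barcodes):
        return pd.DataFrame({"barcode": barcodes, "passed_qc": [True] * len(barcodes)})

    def test_passenger_free_definition_and_complement(self):
        profiles = self._profiles(["B1", "B2", "B3", "B4"])
        calls = _calls(
            [
                ("r0", "B2", "U1", "human", "hg1"),
                ("r1", "B2", "U2", "human", "hg2"),
                ("r2", "B3", "U1", "mouse", "g1"),
            ]
        )
        hits = [ReporterHit("r9", "B4", "U9", "GFP", 30)]
        out = flag_passenger_free(profiles, hits, calls)
        by_bc = out.set_index("barcode")
        assert by_bc.loc["B1", "passenger_free"]  # nothing at all
        assert by_bc.loc["B3", "passenger_free"]  # mouse reads only
        assert not by_bc.loc["B2", "passenger_free"]  # 2 human reads
        assert by_bc.loc["B2", "passenger_reads"] == 2
        assert not by_bc.loc["B4", "passenger_free"]  # exactly 1 GFP hit
        assert (out["passenger_free"] == (out["passenger_reads"] == 0)).all()

    def test_passenger_free_fraction_rises_with_time(self, toy_refs, toy_index, tmp_path):
        """Fast decay (h=1): more engulfed cells are passenger-free at 6 h
        than at 2 h, per the truth table."""
        from passenger_tracer import (
            SimulationParams,
            classify_fastq,
            run_rescue,
            simulate_experiment,
        )

        params = SimulationParams(
            n_cells_per_condition=50,
            conditions=(("AC_2h", 2.0), ("AC_6h", 6.0)),
            reads_per_cell=60.0,
            decay_half_life_hours=1.0,
            ambient_rate=0.0,
            error_rate=0.0,
            rng_seed=61,
        )
        sim = simulate_experiment(toy_refs, params, tmp_path)
        free_frac = {}
        for cond in ("AC_2h", "AC_6h"):
            r1, r2 = sim.fastq_paths[cond]
            calls, _ = classify_fastq(r1, r2, toy_index)
            matrix = build_matrix(calls, sim.whitelist)
            profiles, _ = qc_filter(
                matrix, toy_refs.mito_gene_ids, QCThresholds(min_genes=5, novelty_min=0.3)
            )
            hits, _ = run_rescue(
                calls, r2, sim.reference_paths["reporter"], sim.whitelist, condition=cond
            )
            profiles = flag_passenger_free(profiles, hits, calls)
            engulfed = set(
                sim.truth_cells.loc[
                    (sim.truth_cells["condition"] == cond) & sim.truth_cells["engulfed"],
                    "barcode",
                ]
            )
            sub = profiles[profiles["barcode"].isin(engulfed)]
            free_frac[cond] = sub["passenger_free"].mean()
        assert free_frac["AC_6h"] > free_frac["AC_2h"]


class TestMatrixIO:
    def test_matrixmarket_roundtrip(self, tmp_path):
        calls = _calls(
            [
                ("r0", "B1", "U1", "mouse", "g1"),
                ("r1", "B1", "U2", "mouse", "g2"),
                ("r2", "B2", "U1", "mouse", "g1"),
            ]
        )
        m = build_matrix(calls, ["B1", "B2"])
        m.write(tmp_path)
        import scipy.io

        loaded = scipy.io.mmread(tmp_path / "matrix.mtx")
        assert (loaded.toarray() == m.counts.toarray()).all()
        assert (tmp_path / "barcodes.tsv").read_text().split() == list(m.barcodes)
        assert (tmp_path / "genes.tsv").read_text().split() == list(m.gene_ids)
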