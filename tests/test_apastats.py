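import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pacpipe import apastats
from pacpipe.apastats import (
    CATEGORY_BOTH,
    CATEGORY_LENGTHENING,
    CATEGORY_SHORTENING,
    CATEGORY_SPLICING,
    UndefinedStatistic,
    classify_event,
    compute_pdu,
    gene_counts,
    pdu_from_usage,
    pdui_from_intensities,
    size_factors,
    usage_table,
)
from pacpipe.apastats import test_gene_de as gene_de
from pacpipe.apastats import test_pac_usage as pac_usage
from pacpipe.config import PipelineConfig

from .oracles import median_of_ratios

SAMPLES = [f"{c}_{r}" for c in ("control", "treated") for r in (1, 2, 3)]


def make_pacs(rows):
    columns = ["pac_id", "gene_id", "region", "exon_index", "dist_from_stop",
               *SAMPLES]
    return pd.DataFrame(rows, columns=columns)


def two_pac_gene(counts_by_sample, dists=(300, 1500), gene="g1",
                 region="UTR3_last_exon"):
    rows = []
    for i, dist in enumerate(dists):
        rows.append(
            (f"{gene}:P{i}", gene, region, 1, dist,
             *[counts_by_sample[s][i] for s in SAMPLES])
        )
    return make_pacs(rows)


class TestGeneCounts:
    def test_sums_pac_counts(self):
        pacs = make_pacs(
            [("p1", "g", "UTR3_last_exon", 1, 100, 10, 1, 1, 1, 1, 1),
             ("p2", "g", "UTR3_last_exon", 1, 500, 20, 1, 1, 1, 1, 1)]
        )
        counts = gene_counts(pacs, SAMPLES)
        assert counts.loc["g", SAMPLES[0]] == 30

    def test_unassigned_pacs_dropped(self):
        pacs = make_pacs([("p1", None, "intergenic", None, np.nan,
                           5, 5, 5, 5, 5, 5)])
        assert gene_counts(pacs, SAMPLES).empty

    def test_conservation_on_random_tables(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            n = int(rng.integers(1, 20))
            pacs = make_pacs(
                [(f"p{i}", f"g{rng.integers(5)}", "UTR3_last_exon", 1,
                  100.0 * (i + 1), *rng.integers(0, 50, size=6).tolist())
                 for i in range(n)]
            )
            counts = gene_counts(pacs, SAMPLES)
            assert counts.to_numpy().sum() == pacs[SAMPLES].to_numpy().sum()


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({s: [10, 20, 30] * 4 for s in SAMPLES})
        assert size_factors(counts).round(12).eq(1.0).all()

    def test_doubled_sample_doubles_factor(self):
        base = np.arange(1, 25)
        counts = pd.DataFrame({"a": base, "b": base * 2})
        f = size_factors(counts)
        assert f["b"] / f["a"] == pytest.approx(2.0)

    def test_matches_median_of_ratios_oracle(self):
        rng = np.random.default_rng(32)
        for _ in range(50):
            mat = rng.integers(1, 200, size=(30, 4))
            counts = pd.DataFrame(mat, columns=list("abcd"))
            np.testing.assert_allclose(
                size_factors(counts).to_numpy(),
                median_of_ratios(mat.astype(float)),
            )

    def test_fallback_to_totals_with_sparse_table(self):
        rng = np.random.default_rng(33)
        mat = rng.integers(0, 5, size=(20, 3))
        mat[:, 2] *= 3
        mat[rng.random(size=20) < 0.9, 0] = 0  # <10 zero-free genes
        counts = pd.DataFrame(mat, columns=list("abc"))
        f = size_factors(counts)
        totals = counts.sum()
        assert f["c"] / f["b"] == pytest.approx(totals["c"] / totals["b"])

    def test_all_zero_rejected(self):
        with pytest.raises(UndefinedStatistic):
            size_factors(pd.DataFrame({"a": [0], "b": [0]}))


def de_design(n_rep):
    samples = [f"{c}_{r}" for c in ("control", "treated")
               for r in range(1, n_rep + 1)]
    return pd.DataFrame(
        {"sample_id": samples,
         "condition": [s.rsplit("_", 1)[0] for s in samples],
         "replicate": [int(s.rsplit("_", 1)[1]) for s in samples]}
    )


class TestGeneDE:
    def _table(self, gene_rows, n_rep=4):
        rng = np.random.default_rng(34)
        design = de_design(n_rep)
        base = {
            f"bg{i}": [100] * (2 * n_rep) for i in range(12)
        }
        base.update(gene_rows)
        counts = pd.DataFrame(base).T
        counts.columns = design["sample_id"]
        return counts, design

    def test_fold_change_exactly_at_threshold_not_called(self, config):
        # condition means 1999.5 vs 2999.5 -> fold change exactly 1.5
        counts, design = self._table(
            {"gene": [1999, 2000, 2000, 1999, 2999, 3000, 3000, 2999]}
        )
        res = gene_de(counts, design, config)
        row = res.loc["gene"]
        assert row.fold_change == pytest.approx(1.5, abs=1e-12)
        assert row.padj < config.padj_max
        assert not row.called

    def test_fold_change_above_threshold_called(self, config):
        counts, design = self._table(
            {"gene": [1999, 2000, 2000, 1999, 3299, 3300, 3300, 3299]}
        )
        assert gene_de(counts, design, config).loc["gene"].called

    def test_downregulation_called_symmetrically(self, config):
        counts, design = self._table(
            {"gene": [3299, 3300, 3300, 3299, 1999, 2000, 2000, 1999]}
        )
        row = gene_de(counts, design, config).loc["gene"]
        assert row.called and row.log2fc < 0

    def test_single_replicate_rejected(self, config):
        counts = pd.DataFrame({"control_1": [10], "treated_1": [12]},
                              index=["g"])
        with pytest.raises(ValueError, match="replicate"):
            gene_de(counts, de_design(1), config)

    def test_identical_conditions_yield_no_calls(self, config):
        rng = np.random.default_rng(35)
        mat = rng.negative_binomial(20, 20 / 120, size=(300, 6))
        counts = pd.DataFrame(mat, columns=de_design(3)["sample_id"])
        res = gene_de(counts, de_design(3), config)
        # null by construction: false-call fraction within the nominal rate
        assert res.called.mean() <= config.padj_max


def usage_from_counts(counts_by_sample, **kwargs):
    pacs = two_pac_gene(counts_by_sample, **kwargs)
    return usage_table(pacs, SAMPLES)


class TestPacUsage:
    def test_identical_usage_not_significant(self, config, design_3v3):
        counts = {s: (30, 70) for s in SAMPLES}
        usage = usage_from_counts(counts)
        res = pac_usage(usage, design_3v3, config)
        assert (res.frac_change == 0).all()
        assert not res.significant.any()

    def test_boundary_change_is_inclusive(self, design_3v3):
        # binary-exact threshold and usages: |frac change| == threshold
        config = PipelineConfig(usage_change_min=0.125)
        control = [0.250, 0.265625, 0.234375]
        treated = [u + 0.125 for u in control]
        rows = []
        for i in range(2):
            u = [1 - c if i == 0 else c
                 for c in control] + [1 - t if i == 0 else t for t in treated]
            rows.append(("g:P%d" % i, "g", "UTR3_last_exon", 1,
                         300 if i == 0 else 1500, *u))
        usage = make_pacs(rows).rename(
            columns={s: f"usage_{s}" for s in SAMPLES}
        )
        usage["occupancy"] = 0.5
        res = pac_usage(usage, design_3v3, config)
        distal = res.set_index("pac_id").loc["g:P1"]
        assert distal.frac_change == 0.125
        assert distal.padj < config.padj_max
        assert distal.significant

    def test_sub_occupancy_pacs_untested(self, config, design_3v3):
        counts = {s: (97, 3) for s in SAMPLES}  # distal occupancy 3%
        usage = usage_from_counts(counts)
        res = pac_usage(usage, design_3v3, config)
        assert res.empty  # gene has <2 occupancy-passing PACs

    def test_zero_total_replicate_treated_missing(self, config, design_3v3):
        counts = {
            "control_1": (40, 60), "control_2": (42, 58), "control_3": (0, 0),
            "treated_1": (50, 50), "treated_2": (52, 48), "treated_3": (48, 52),
        }
        usage = usage_from_counts(counts)
        res = pac_usage(usage, design_3v3, config)
        assert res.tested.all()  # two informative control replicates remain
        assert (res.p < 1).all()

    def test_single_informative_replicate_gives_p_one(self, config):
        design = de_design(2)
        samples = design["sample_id"].tolist()
        rows = []
        for i, dist in enumerate((300, 1500)):
            vals = [(40, 60)[i], 0, (45, 55)[i], (45, 55)[i]]
            rows.append((f"g:P{i}", "g", "UTR3_last_exon", 1, dist, *vals))
        pacs = pd.DataFrame(
            rows, columns=["pac_id", "gene_id", "region", "exon_index",
                           "dist_from_stop", *samples]
        )
        usage = usage_table(pacs, samples)
        res = pac_usage(usage, design, config)
        assert (res.p == 1).all()
        assert not res.significant.any()


class TestPdu:
    def test_two_pac_reduces_to_lu_over_lu_plus_su(self):
        assert pdu_from_usage(np.array([0.63, 0.37]),
                              np.array([300.0, 1500.0])) == pytest.approx(0.37)

    def test_equal_usage_gives_half(self):
        assert pdu_from_usage(np.array([5.0, 5.0]),
                              np.array([0.0, 800.0])) == 0.5

    def test_three_pac_distance_weighting(self):
        # d = 0/500/1000, usage 0.50/0.25/0.25 -> 0.5*0 + 0.25*0.5 + 0.25*1
        got = pdu_from_usage(np.array([0.5, 0.25, 0.25]),
                             np.array([0.0, 500.0, 1000.0]))
        assert got == pytest.approx(0.375)

    def test_fewer_than_two_pacs_undefined(self):
        with pytest.raises(UndefinedStatistic):
            pdu_from_usage(np.array([1.0]), np.array([100.0]))

    @settings(max_examples=200, derandomize=True)
    @given(
        lu=st.integers(0, 10_000),
        su=st.integers(0, 10_000),
    )
    def test_two_pac_identity_for_all_counts(self, lu, su):
        if lu + su == 0:
            return
        got = pdu_from_usage(np.array([su, lu], dtype=float),
                             np.array([200.0, 1700.0]))
        assert abs(got - lu / (lu + su)) < 1e-12
        assert 0.0 <= got <= 1.0

    def test_compute_pdu_uses_condition_mean_usage(self, config, design_3v3):
        counts = {
            "control_1": (63, 37), "control_2": (63, 37), "control_3": (63, 37),
            "treated_1": (45, 55), "treated_2": (45, 55), "treated_3": (45, 55),
        }
        usage = usage_from_counts(counts)
        assert compute_pdu(usage, design_3v3, "control", config) == \
            pytest.approx(0.37)
        assert compute_pdu(usage, design_3v3, "treated", config) == \
            pytest.approx(0.55)

    def test_compute_pdu_requires_last_exon(self, config, design_3v3):
        counts = {s: (40, 60) for s in SAMPLES}
        usage = usage_from_counts(counts, region="internal_exon")
        with pytest.raises(UndefinedStatistic):
            compute_pdu(usage, design_3v3, "control", config)


class TestPduiFromIntensities:
    def test_equal_bands_give_half(self):
        assert pdui_from_intensities(5.0, 5.0) == 0.5

    def test_all_long_gives_one(self):
        assert pdui_from_intensities(3.0, 0.0) == 1.0

    def test_direct_arithmetic(self):
        assert pdui_from_intensities(30.0, 70.0) == pytest.approx(0.30)

    def test_loading_normalization(self):
        # distorted loading is corrected before the ratio
        assert pdui_from_intensities(60.0, 70.0, loading_lu=2.0,
                                     loading_su=1.0) == pytest.approx(0.30)

    def test_zero_denominator_signalled(self):
        with pytest.raises(UndefinedStatistic):
            pdui_from_intensities(0.0, 0.0)


def run_classification(pacs, config, design):
    usage = usage_table(pacs, SAMPLES)
    tests = pac_usage(usage, design, config)
    return classify_event("g1", usage, tests, design, config)


class TestClassifyEvent:
    def test_distal_gain_is_lengthening(self, config, design_3v3):
        counts = {s: (63, 37) if s.startswith("control") else (45, 55)
                  for s in SAMPLES}
        event = run_classification(two_pac_gene(counts), config, design_3v3)
        assert event.category == CATEGORY_LENGTHENING
        assert event.delta_pdu == pytest.approx(0.18)

    def test_distal_loss_is_shortening(self, config, design_3v3):
        counts = {s: (45, 55) if s.startswith("control") else (63, 37)
                  for s in SAMPLES}
        event = run_classification(two_pac_gene(counts), config, design_3v3)
        assert event.category == CATEGORY_SHORTENING
        assert event.delta_pdu == pytest.approx(-0.18)

    def test_middle_pac_shift_is_both(self, config, design_3v3):
        rows = []
        control, treated = (30, 40, 30), (30, 15, 55)
        for i, dist in enumerate((200, 900, 1600)):
            vals = [control[i]] * 3 + [treated[i]] * 3
            rows.append((f"g1:P{i}", "g1", "UTR3_last_exon", 1, dist, *vals))
        event = run_classification(make_pacs(rows), config, design_3v3)
        assert event.category == CATEGORY_BOTH

    def test_pacs_in_two_exons_is_splicing(self, config, design_3v3):
        rows = []
        control, treated = (30, 70), (60, 40)
        for i, (region, exon, dist) in enumerate(
            [("internal_exon", 0, np.nan), ("UTR3_last_exon", 1, 500.0)]
        ):
            vals = [control[i]] * 3 + [treated[i]] * 3
            rows.append((f"g1:P{i}", "g1", region, exon, dist, *vals))
        event = run_classification(make_pacs(rows), config, design_3v3)
        assert event.category == CATEGORY_SPLICING

    def test_low_occupancy_pac_ignored(self, config, design_3v3):
        # the 4%-occupancy intronic PAC must not force a splicing verdict
        rows = []
        control, treated = (60, 36, 4), (36, 60, 4)
        for i, (region, exon, dist) in enumerate(
            [("UTR3_last_exon", 1, 300.0), ("UTR3_last_exon", 1, 1500.0),
             ("intron", None, np.nan)]
        ):
            vals = [control[i]] * 3 + [treated[i]] * 3
            rows.append((f"g1:P{i}", "g1", region, exon, dist, *vals))
        event = run_classification(make_pacs(rows), config, design_3v3)
        assert event.category == CATEGORY_LENGTHENING
        assert len(event.pac_records) == 2

    def test_no_significant_shift_no_event(self, config, design_3v3):
        counts = {s: (63, 37) for s in SAMPLES}
        assert run_classification(two_pac_gene(counts), config, design_3v3) is None


class TestUsageNormalization:
    def test_per_sample_usage_sums_to_one(self, small_dataset):
        from pacpipe.pipeline import run_pipeline  # noqa: PLC0415

        path, truth = small_dataset
        usage = usage_table_from_dataset(path, truth)
        for s in truth.samples:
            sums = usage.groupby("gene_id")[f"usage_{s}"].sum()
            nonzero = sums[sums > 0]
            np.testing.assert_allclose(nonzero, 1.0, atol=1e-9)


def usage_table_from_dataset(path, truth):
    from pacpipe import clusters as cl, sites as si
    from pacpipe.formats_io import read_design, read_end_records, read_gene_models
    from pyfaidx import Fasta

    config = PipelineConfig()
    design = read_design(path / "design.tsv")
    records = pd.concat(
        [read_end_records(path / f"reads_{s}.bed", s)
         for s in design["sample_id"]], ignore_index=True,
    )
    called = si.call_polya_sites(records, config, design["sample_id"].tolist())
    called = si.filter_internal_priming(called, Fasta(str(path / "genome.fa")),
                                        config)
    pacs = cl.annotate_pacs(cl.cluster_sites(called, config),
                            read_gene_models(path / "annotation.gtf"))
    return usage_table(pacs, design["sample_id"].tolist())
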