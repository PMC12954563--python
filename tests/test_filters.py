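"""The V0/V1 cascade against a hand-built toy callset and a naive oracle.

The toy exercises every rule at its boundary: QD/MQ/MQRankSum at and
below threshold, HDplot H at 0.6/0.7 and D at 10.0/10.4, genotype DP
5/6/7 and GQ 19/20, minor-allele read sums of 2 and 3, the half-sample
depth rule, invariant DP rules and sample missingness.  Expected fates
were enumerated by hand when each site was designed, and the whole
cascade is independently re-evaluated by a literal per-site/per-rule
loop (`naive_cascade`).
"""

import math

import numpy as np
import pytest

from spetkit import filters
from spetkit.filters import FilterConfig, apply_filter_workflow, build_v1
from spetkit.variants import read_vcf, write_vcf

from conftest import make_table

SAMPLES = [f"s{i}" for i in range(10)]


def _site(pos, gt, dp, gq, adr, ada, expect, qd=25.0, mq=60.0, mqrs=0.0,
          alt="T", multiallelic=False):
    return {
        "pos": pos, "alt": alt, "qd": qd, "mq": mq, "mqranksum": mqrs,
        "multiallelic": multiallelic,
        "gt": gt, "dp": dp, "gq": gq, "ad_ref": adr, "ad_alt": ada,
        "expect": expect,
    }


def _clean(pos, s9_called=False, expect=("retained",), **kw):
    """Baseline biallelic SNP: 2 hets, 2 hom-alts, rest hom-ref, DP 30."""
    gt = [0, 0, 0, 0, 0, 1, 1, 2, 2, 0]
    adr = [30, 30, 30, 30, 30, 15, 15, 0, 0, 30]
    ada = [0, 0, 0, 0, 0, 15, 15, 30, 30, 0]
    dp = [30] * 10
    gq = [99] * 10
    if not s9_called:
        gt = gt[:9] + [-1]
    return _site(pos, gt, dp, gq, adr, ada, expect, **kw)


def _inv(pos, dp, expect):
    return {
        "pos": pos, "alt": "", "gt": [0 if d > 0 else -1 for d in dp],
        "dp": dp, "gq": [-1] * 10, "ad_ref": [-1] * 10, "ad_alt": [-1] * 10,
        "expect": expect,
    }


def build_toy():
    """50 sites whose fates were enumerated by hand at design time."""
    rows = []
    # --- hard site filter boundaries (strict inequalities) ---
    rows.append(_clean(100, qd=1.9, expect=("hard_filter",)))
    rows.append(_clean(110, qd=2.0, expect=("retained",)))
    rows.append(_clean(120, mq=39.9, expect=("hard_filter",)))
    rows.append(_clean(130, mq=40.0, expect=("retained",)))
    rows.append(_clean(140, mqrs=-12.6, expect=("hard_filter",)))
    rows.append(_clean(150, mqrs=-12.5, expect=("retained",)))
    rows.append(_clean(160, qd=None, mq=None, mqrs=None, expect=("retained",)))

    # --- HDplot: s9 called in this block ---
    # 7/10 hets: H = 0.7 > 0.6
    rows.append(_site(200, [1] * 7 + [0] * 3, [30] * 10, [99] * 10,
                      [15] * 7 + [30] * 3, [15] * 7 + [0] * 3, ("hdplot",)))
    # 6/10 hets: H = 0.6 exactly -> pass
    rows.append(_site(210, [1] * 6 + [0] * 4, [30] * 10, [99] * 10,
                      [15] * 6 + [30] * 4, [15] * 6 + [0] * 4, ("retained",)))
    # 4 hets at AD 75/25: ratio 0.75, D = 200/20 = 10.0 exactly -> pass
    rows.append(_site(220, [1] * 4 + [0] * 6, [100] * 4 + [30] * 6, [99] * 10,
                      [75] * 4 + [30] * 6, [25] * 4 + [0] * 6, ("retained",)))
    # 4 hets at AD 76/24: D = 208/20 = 10.4 -> flagged
    rows.append(_site(230, [1] * 4 + [0] * 6, [100] * 4 + [30] * 6, [99] * 10,
                      [76] * 4 + [30] * 6, [24] * 4 + [0] * 6, ("hdplot",)))
    # 2 hets at AD 19/81: ratio = 38/200 = 0.19 < 0.2 -> flagged
    rows.append(_site(240, [1, 1] + [2] * 8, [100, 100] + [30] * 8, [99] * 10,
                      [19, 19] + [0] * 8, [81, 81] + [30] * 8, ("hdplot",)))
    # no heterozygotes: ratio/D undefined, H rule only -> pass
    rows.append(_site(250, [0] * 5 + [2] * 5, [30] * 10, [99] * 10,
                      [30] * 5 + [0] * 5, [0] * 5 + [30] * 5, ("retained",)))

    # --- genotype-level DP/GQ masking (site retained) ---
    r = _clean(300)
    r["dp"] = [5] + [30] * 9  # s0 masked (DP 5 < 6)
    rows.append(r)
    r = _clean(310)
    r["gq"] = [19, 20] + [99] * 8  # s0 masked (GQ 19), s1 kept at 20
    rows.append(r)

    # --- multiallelic dropped ---
    rows.append(_clean(320, multiallelic=True, expect=("multiallelic",)))

    # --- minor-allele read support: 2 -> dropped, 3 -> kept ---
    rows.append(_site(330, [1] + [0] * 9, [6] + [30] * 9, [99] * 10,
                      [4] + [30] * 9, [2] + [0] * 9, ("low_minor_reads",)))
    rows.append(_site(340, [1] + [0] * 9, [6] + [30] * 9, [99] * 10,
                      [3] + [30] * 9, [3] + [0] * 9, ("retained",)))

    # --- half-sample depth (strictly > 6 in >= half the samples) ---
    # 5/10 at DP 7, rest DP 0: kept
    rows.append(_site(350, [0, 0, 0, 1, 2] + [-1] * 5, [7] * 5 + [0] * 5,
                      [99] * 5 + [-1] * 5, [7, 7, 7, 3, 0] + [-1] * 5,
                      [0, 0, 0, 4, 7] + [-1] * 5, ("retained",)))
    # only 4/10 above 6 (six samples at exactly DP 6): dropped
    rows.append(_site(360, [1, 1, 2, 2] + [0] * 6, [30] * 4 + [6] * 6, [99] * 10,
                      [15, 15, 0, 0] + [6] * 6, [15, 15, 30, 30] + [0] * 6,
                      ("low_half_depth",)))
    # all DP exactly 6: dropped
    rows.append(_site(370, [0] * 8 + [1, 2], [6] * 10, [99] * 10,
                      [6] * 8 + [3, 0], [0] * 8 + [3, 6], ("low_half_depth",)))

    # --- interaction: hard fail AND HDplot fail ---
    rows.append(_site(380, [1] * 7 + [0] * 3, [30] * 10, [99] * 10,
                      [15] * 7 + [30] * 3, [15] * 7 + [0] * 3,
                      ("hard_filter", "hdplot"), qd=1.0))

    # --- invariant sites ---
    rows.append(_inv(400, [10] * 10, ("inv_kept",)))
    rows.append(_inv(410, [6] * 10, ("low_half_depth",)))
    rows.append(_inv(420, [7] * 5 + [0] * 5, ("inv_kept",)))

    # --- an indel-like record: discarded before any rule ---
    rows.append({"pos": 430, "ref": "A", "alt": "AT", "gt": [0] * 10,
                 "dp": [30] * 10, "gq": [99] * 10, "ad_ref": [-1] * 10,
                 "ad_alt": [-1] * 10, "expect": ("discarded",)})

    # --- filler clean SNPs and invariants up to 50 sites ---
    pos = 500
    while len(rows) < 47:
        rows.append(_clean(pos))
        pos += 10
    rows.append(_inv(800, [20] * 10, ("inv_kept",)))
    rows.append(_inv(810, [20] * 10, ("inv_kept",)))
    rows.append(_inv(820, [4] * 10, ("low_half_depth",)))
    assert len(rows) == 50
    return rows


def naive_cascade(rows, cfg=None):
    """Independent per-site transcription of every rule (plain loops).

    Returns (snp_flags: pos -> set of flags, kept_invariant_pos,
    removed_samples) evaluated in workflow order on the full cohort.
    """
    cfg = cfg or FilterConfig()
    n = len(SAMPLES)
    snp_flags = {}
    kept_inv = []
    snp_rows = []
    for r in rows:
        if r.get("alt", "") == "":
            # invariant rule
            deep = sum(1 for d in r["dp"] if d > cfg.half_sample_dp)
            if deep * 2 >= n:
                kept_inv.append(r["pos"])
            continue
        if len(r.get("ref", "A")) > 1 or len(r["alt"]) > 1:
            continue  # non-SNP record, discarded
        snp_rows.append(r)
        flags = set()
        # hard site filter (NaN never fails)
        for key, thr in (("qd", cfg.qd_min), ("mq", cfg.mq_min),
                         ("mqranksum", cfg.mqranksum_min)):
            v = r.get(key)
            if v is not None and not (isinstance(v, float) and math.isnan(v)) and v < thr:
                flags.add("hard_filter")
        # HDplot on raw genotypes
        called = [g for g in r["gt"] if g >= 0]
        hets = [i for i, g in enumerate(r["gt"]) if g == 1]
        if called:
            h = len(hets) / len(called)
            if h > cfg.hdplot.h_max:
                flags.add("hdplot")
        a = sum(r["ad_ref"][i] for i in hets if r["ad_ref"][i] >= 0)
        b = sum(r["ad_alt"][i] for i in hets if r["ad_alt"][i] >= 0)
        if a + b > 0:
            ratio = a / (a + b)
            d = (a - b) / math.sqrt(a + b)
            if not (cfg.hdplot.raf_min <= ratio <= cfg.hdplot.raf_max):
                flags.add("hdplot")
            if not (cfg.hdplot.d_min <= d <= cfg.hdplot.d_max):
                flags.add("hdplot")
        # genotype masking, then locus support rules
        gt2 = []
        for i in range(n):
            g = r["gt"][i]
            if r["dp"][i] >= 0 and r["dp"][i] < cfg.dp_min:
                g = -1
            if r["gq"][i] >= 0 and r["gq"][i] < cfg.gq_min:
                g = -1
            gt2.append(g)
        r["_gt_masked"] = gt2
        if r.get("multiallelic"):
            flags.add("multiallelic")
        deep = sum(1 for d in r["dp"] if d > cfg.half_sample_dp)
        if deep * 2 < n:
            flags.add("low_half_depth")
        alt_count = sum(g for g in gt2 if g >= 0)
        ref_count = sum(2 - g for g in gt2 if g >= 0)
        minor_alt = alt_count <= ref_count
        minor_reads = sum(
            (r["ad_alt"][i] if minor_alt else r["ad_ref"][i])
            for i in range(n)
            if gt2[i] >= 0 and (r["ad_alt"][i] if minor_alt else r["ad_ref"][i]) >= 0
        )
        if minor_reads < cfg.minor_reads_min:
            flags.add("low_minor_reads")
        snp_flags[r["pos"]] = flags
    # sample missingness over retained SNP sites (post-masking)
    retained = [r for r in snp_rows if not snp_flags[r["pos"]]]
    removed = []
    for i, s in enumerate(SAMPLES):
        miss = sum(1 for r in retained if r["_gt_masked"][i] < 0)
        if retained and miss / len(retained) > cfg.sample_missing_max:
            removed.append(s)
    return snp_flags, kept_inv, removed


@pytest.fixture(scope="module")
def toy():
    rows = build_toy()
    return rows, make_table(rows, SAMPLES)


class TestCascadeOracle:
    def test_flags_match_hand_enumeration(self, toy):
        rows, table = toy
        res = apply_filter_workflow(table)
        snp_pos = res.snps.sites["pos"].to_numpy()
        flag_names = ("hard_filter", "hdplot", "multiallelic",
                      "low_half_depth", "low_minor_reads")
        got = {
            int(p): {nm for nm in flag_names if res.snps.flags[nm][i]}
            for i, p in enumerate(snp_pos)
        }
        for r in rows:
            exp = set(r["expect"]) - {"retained", "inv_kept", "discarded"}
            if r.get("alt", "") == "" or "discarded" in r["expect"]:
                assert r["pos"] not in got
            else:
                assert got[r["pos"]] == exp, f"site {r['pos']}"

    def test_matches_naive_cascade(self, toy):
        rows, table = toy
        res = apply_filter_workflow(table)
        exp_flags, exp_inv, exp_removed = naive_cascade(
            [dict(r) for r in rows]
        )
        snp_pos = res.snps.sites["pos"].to_numpy()
        flag_names = ("hard_filter", "hdplot", "multiallelic",
                      "low_half_depth", "low_minor_reads")
        got = {
            int(p): {nm for nm in flag_names if res.snps.flags[nm][i]}
            for i, p in enumerate(snp_pos)
        }
        assert got == exp_flags
        v0_inv = res.v0.sites[res.v0.sites["site_class"] == "invariant"]
        assert sorted(v0_inv["pos"]) == sorted(exp_inv)
        assert set(SAMPLES) - set(res.retained_samples) == set(exp_removed)

    def test_v0_contents(self, toy):
        rows, table = toy
        res = apply_filter_workflow(table)
        exp = sorted(
            r["pos"] for r in rows if r["expect"] in (("retained",), ("inv_kept",))
        )
        assert sorted(res.v0.sites["pos"]) == exp
        assert res.v0.samples == [f"s{i}" for i in range(9)]  # s9 removed
        # coordinate sorted
        assert res.v0.sites["pos"].is_monotonic_increasing

    def test_conservation(self, toy):
        rows, table = toy
        res = apply_filter_workflow(table)
        rep = dict(zip(res.report["stage"], res.report["count"]))
        assert rep["snps_in"] + rep["invariants_in"] + rep["discarded_other"] == 50

    def test_vcf_round_trip_same_result(self, toy, tmp_path):
        rows, table = toy
        biallelic = table.take_sites(~table.sites["multiallelic"].to_numpy(bool))
        path = tmp_path / "toy.vcf"
        write_vcf(biallelic, path)
        back, discarded = read_vcf(path)
        res_mem = apply_filter_workflow(biallelic)
        res_vcf = apply_filter_workflow(back)
        assert sorted(res_vcf.v0.sites["pos"]) == sorted(res_mem.v0.sites["pos"])
        assert res_vcf.retained_samples == res_mem.retained_samples


class TestIndividualRules:
    def test_missingness_boundary(self):
        # 10 sites; 8 missing = 0.80 kept (strict >), 9 missing removed
        rows = []
        for k in range(10):
            gt = [0, 0, 0]
            if k < 8:
                gt[1] = -1
            if k < 9:
                gt[2] = -1
            rows.append({"pos": 10 + k, "alt": "T", "gt": gt,
                         "dp": [30] * 3, "gq": [99] * 3,
                         "ad_ref": [30] * 3, "ad_alt": [0] * 3})
        table = make_table(rows, ["a", "b", "c"])
        kept, report = filters.sample_missingness_filter(table, FilterConfig())
        assert kept == ["a", "b"]

    def test_all_samples_removed_errors(self):
        rows = [{"pos": 1, "alt": "T", "gt": [-1, -1], "dp": [30, 30],
                 "gq": [99, 99], "ad_ref": [-1, -1], "ad_alt": [-1, -1]}]
        with pytest.raises(ValueError, match="all samples"):
            filters.sample_missingness_filter(
                make_table(rows, ["a", "b"]), FilterConfig()
            )

    def test_monotonicity_tightening_thresholds(self, medium_cohort):
        base = apply_filter_workflow(medium_cohort.table.copy())
        tight = FilterConfig(dp_min=10, gq_min=30, minor_reads_min=5)
        tighter = apply_filter_workflow(medium_cohort.table.copy(), tight)
        assert tighter.v0.n_sites <= base.v0.n_sites
        assert (tighter.v0.gt >= 0).sum() <= (base.v0.gt >= 0).sum()

    def test_build_v1_drops_samples(self, toy):
        rows, table = toy
        v0 = apply_filter_workflow(table).v0
        v1 = build_v1(v0, [v0.samples[0]])
        assert len(v1.samples) == len(v0.samples) - 1
        assert v0.samples[0] not in v1.samples

    def test_build_v1_empty_list_identity(self, toy):
        rows, table = toy
        v0 = apply_filter_workflow(table).v0
        v1 = build_v1(v0, [])
        assert v1.samples == v0.samples and v1.n_sites == v0.n_sites

    def test_build_v1_unknown_sample(self, toy):
        rows, table = toy
        v0 = apply_filter_workflow(table).v0
        with pytest.raises(KeyError, match="unknown"):
            build_v1(v0, ["nope"])

    def test_hdplot_arithmetic(self):
        # A=30, B=10: ratio 0.75, D = 20/sqrt(40)
        rows = [{"pos": 1, "alt": "T", "gt": [1, 0], "dp": [40, 30],
                 "gq": [99, 99], "ad_ref": [30, 30], "ad_alt": [10, 0]}]
        table = make_table(rows, ["a", "b"])
        s = filters.hdplot(table)
        assert s.ratio[0] == pytest.approx(0.75)
        assert s.d[0] == pytest.approx(20 / math.sqrt(40))
        assert s.h[0] == pytest.approx(0.5)
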