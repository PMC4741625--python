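"""Benchmark routines exercising each pipeline stage on planted synthetic data.

Each function regenerates its inputs from a seed, runs the corresponding
pipeline stage, and measures recovery or agreement.  The printed tables of the
lung-adenocarcinoma study (target-category counts, module-coverage pairs, Venn
counts) are treated as inputs to the arithmetic operations they exercise.
"""

from __future__ import annotations

import dataclasses
from math import log
from typing import Sequence

import numpy as np

from . import modules as cm
from . import pwm as pw
from . import regulators as mr
from . import simulate as sim
from .expression import DEGCriteria, TUMOR_CRITERIA, breakdown_from_counts, compute_deg

# printed per-category gene counts (up-regulated tumor genes): total gene count
# and count carrying Myc binding sites
TABLE1_COUNTS = {"T": 32, "rT": 15, "R": 16, "rR": 9, "new": 90}
TABLE1_SITE_COUNTS = {"T": 20, "rT": 5, "R": 8, "rR": 2, "new": 32}

# printed (n_fit, n_total) pairs: per-factor consensus-site coverage and the
# full composite-module fit, for the up-regulated (N=27) and the two
# down-regulated (N=24) modules
COVERAGE_PAIRS = {
    "up_myc": (20, 27), "up_elf5": (26, 27), "up_cebpa": (25, 27), "up_module": (17, 27),
    "down_a_myc": (15, 24), "down_a_klf7": (16, 24), "down_a_gata3": (23, 24), "down_a_module": (11, 24),
    "down_b_myc": (22, 24), "down_b_sox18": (22, 24), "down_b_p53": (23, 24), "down_b_module": (20, 24),
}


def table1_breakdown():
    """Category breakdown recomputed from the printed per-category counts."""
    return breakdown_from_counts(TABLE1_COUNTS, TABLE1_SITE_COUNTS)


def coverage_percentages() -> dict[str, int]:
    return {k: cm.coverage_percentage(n, d) for k, (n, d) in COVERAGE_PAIRS.items()}


def reference_match_score(pwm: pw.PWM, window: str) -> tuple[float, float]:
    """Naive per-position reference implementation of the information-vector score."""

    def score(freq_rows, chars):
        iv, cur, lo, hi = [], 0.0, 0.0, 0.0
        for row, c in zip(freq_rows, chars):
            i = sum(f * log(4 * f) for f in row if f > 0)
            f_c = min(row) if c == "N" else row["ACGT".index(c)]
            cur += i * f_c
            lo += i * min(row)
            hi += i * max(row)
        return 1.0 if hi == lo else (cur - lo) / (hi - lo)

    rows = [list(r) for r in pwm.freq]
    core = slice(pwm.core_start, pwm.core_start + pw.CORE_LENGTH)
    return score(rows, window), score(rows[core], window[core])


def match_oracle_check(
    n_promoters: int = 200,
    promoter_length: int = 1100,
    n_matrices: int = 3,
    seed: int = 0,
) -> dict[str, float]:
    """Window-by-window agreement of the scanner with the reference scorer.

    Every window of every seeded random promoter is scored on both strands by
    the vectorized scanner and the naive reference; also checks mss = 1 for
    each matrix's consensus and 0 for its anti-consensus.
    """
    rng = np.random.default_rng(seed)
    lib = sim.simulate_pwm_library(n_matrices, seed=seed)
    for p in lib:
        assert pw.match_score(p, p.consensus)[0] == 1.0
        anti = "".join("ACGT"[i] for i in p.freq.argmin(axis=1))
        assert abs(pw.match_score(p, anti)[0]) < 1e-12
    n_windows = n_agree = 0
    for _ in range(n_promoters):
        seq = "".join(rng.choice(list("ACGT"), size=promoter_length))
        for p in lib:
            for s in (seq, pw.reverse_complement(seq)):
                codes = pw._encode(s)
                mss, css = pw._scan_strand(p, codes)
                for off in range(len(s) - len(p) + 1):
                    ref = reference_match_score(p, s[off : off + len(p)])
                    n_windows += 1
                    if abs(mss[off] - ref[0]) < 1e-9 and abs(css[off] - ref[1]) < 1e-9:
                        n_agree += 1
    return {
        "n_windows": n_windows,
        "n_agree": n_agree,
        "agreement_pct": 100.0 * n_agree / n_windows,
        "consensus_ok": True,
    }


def ga_planted_recovery(
    n_seeds: int = 10,
    n_yes: int = 30,
    n_no: int = 100,
    library_size: int = 12,
    seed: int = 0,
) -> dict[str, float]:
    """Planted 3-matrix module: GA recovery rate over independent seeds.

    Per seed: promoters for the YES genes carry one instance of each planted
    matrix (within the planted distance window); NO promoters are pure
    background.  Recovery means the best module's matrix triple equals the
    planted one as a set.
    """
    recovered = 0
    for s in range(n_seeds):
        data_seed = seed * 1000 + s
        lib = sim.simulate_pwm_library(library_size, seed=data_seed)
        planted = [p.id for p in lib[:3]]
        yes = [f"y{i}" for i in range(n_yes)]
        no = [f"n{i}" for i in range(n_no)]
        planting = {
            m: sim.PlantingSpec(genes=tuple(yes), probability=1.0, score_floor=0.9)
            for m in planted
        }
        proms, _ = sim.simulate_promoters(yes + no, lib, planting, max_span=100, seed=data_seed)
        ga_pwms = [dataclasses.replace(p, core_cutoff=0.5, matrix_cutoff=0.5) for p in lib]
        idx = cm.index_hits(pw.scan_promoters(ga_pwms, proms))
        empty: dict = {}
        best, _ = cm.run_ga(
            cm.GAConfig.fast(seed=data_seed),
            [p.id for p in lib],
            {g: idx.get(g, empty) for g in yes},
            {g: idx.get(g, empty) for g in no},
        )
        if sorted(best.pwm_ids) == sorted(planted):
            recovered += 1
    return {"n_seeds": n_seeds, "n_recovered": recovered, "recovery_rate": recovered / n_seeds}


def mr_planted_recovery(
    n_seeds: int = 20,
    n_nodes: int = 300,
    n_inputs: int = 27,
    n_wired: int = 18,
    seed: int = 0,
) -> dict[str, float]:
    """Planted hub wired to n_wired of n_inputs at distance 1: recovery rate.

    Recovery means the hub ranks first and passes all three cutoffs
    (score >= 0.2, Z >= 1, FDR q <= 0.05).
    """
    import networkx as nx

    recovered = 0
    for s in range(n_seeds):
        data_seed = seed * 1000 + s
        inputs = [f"g{i}" for i in range(n_inputs)]
        df, truth = sim.simulate_network(
            n_nodes, 2.0, inputs, wired_fraction=n_wired / n_inputs,
            wiring_distance=1, seed=data_seed,
        )
        net = nx.from_pandas_edgelist(df, "source", "target", create_using=nx.DiGraph)
        params = mr.MRParams(
            n_permutations=mr.recommended_permutations(net.number_of_nodes()),
            seed=data_seed,
        )
        results = mr.rank_master_regulators(net, inputs, params)
        top = results[0]
        if top.node == truth.planted_regulator["hub"] and top.passes:
            recovered += 1
    return {"n_seeds": n_seeds, "n_recovered": recovered, "recovery_rate": recovered / n_seeds}


def mr_null_calibration(
    n_nodes: int = 300,
    n_inputs: int = 27,
    seed: int = 0,
) -> dict[str, float]:
    """Input set drawn from the null itself: share of candidates at p <= 0.05."""
    import networkx as nx

    rng = np.random.default_rng(seed)
    df, _ = sim.simulate_network(n_nodes, 2.0, [f"g{i}" for i in range(n_inputs)],
                                 wired_fraction=0.0, seed=seed)
    net = nx.from_pandas_edgelist(df, "source", "target", create_using=nx.DiGraph)
    nodes = sorted(net.nodes)
    null_inputs = list(rng.choice(nodes, size=n_inputs, replace=False))
    table = mr.mr_significance(net, null_inputs, mr.MRParams(n_permutations=2000, seed=seed + 1))
    frac = float((table["p_value"] <= 0.05).mean())
    return {"n_candidates": len(table), "frac_p_le_05": frac}


def deg_filter_recovery(
    n_seeds: int = 5,
    n_genes: int = 400,
    n_per_group: int = 10,
    frac_deg: float = 0.25,
    seed: int = 0,
) -> dict[str, float]:
    """Sensitivity and false-positive rate of the tumor-profile DEG filter.

    The planted effect is a 3-fold shift (log2 FC = log2 3), i.e. exactly at
    the profile's fold-change threshold; sensitivity is the share of planted
    genes recovered, FPR the share of null genes flagged.
    """
    tp = fp = n_planted = n_null = 0
    monotone_ok = True
    for s in range(n_seeds):
        expr, truth = sim.simulate_expression(
            n_genes, n_per_group, float(np.log2(3)), frac_deg, seed=seed * 1000 + s
        )
        planted = set(truth.planted_deg)
        found = {r.gene_id for r in compute_deg(expr, "control", "case", TUMOR_CRITERIA)}
        tp += len(found & planted)
        fp += len(found - planted)
        n_planted += len(planted)
        n_null += n_genes - len(planted)
        relaxed = {
            r.gene_id
            for r in compute_deg(
                expr, "control", "case",
                DEGCriteria(min_abs_fc=2.0, max_p=0.1, min_call_concordance=0.8),
            )
        }
        monotone_ok = monotone_ok and found <= relaxed
    return {
        "sensitivity": tp / n_planted,
        "fpr": fp / n_null,
        "monotone_under_tightening": monotone_ok,
        "n_planted": n_planted,
        "n_null": n_null,
    }
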