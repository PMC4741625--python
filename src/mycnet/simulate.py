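"""Synthetic pipeline inputs with planted, serialized ground truth.

Every generator is a pure function of its parameters and seed, and emulates
one of the four pipeline inputs:

* an expression matrix with detection calls and planted fold-change effects,
* promoter sequences (FASTA + TSS annotation) with motif instances planted
  from PWMs,
* a JASPAR-style matrix library (including an E-box-like Myc matrix),
* a directed interaction network with a planted hub regulator.

Signals follow a log-normal model (log2 signal ~ Normal(8, 1) baseline, the
typical microarray dynamic range); promoter background is i.i.d. at a chosen
GC content.  The truth object records everything planted so that each pipeline
stage can be checked for recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .pwm import BASES, PWM, PromoterRecord, match_score, reverse_complement

PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 100
_BASELINE_LOG2 = 8.0
_BASELINE_SD = 1.0


class SimulationError(ValueError):
    pass


@dataclass
class SyntheticTruth:
    """Planted ground truth, serialized alongside every generated dataset."""

    seed: int
    planted_deg: dict[str, float] = field(default_factory=dict)  # gene -> true log2 effect
    planted_motifs: list[dict] = field(default_factory=list)  # gene/pwm/offset/strand
    planted_module: dict | None = None
    planted_regulator: dict | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "seed": self.seed,
                    "planted_deg": self.planted_deg,
                    "planted_motifs": self.planted_motifs,
                    "planted_module": self.planted_module,
                    "planted_regulator": self.planted_regulator,
                },
                indent=2,
            )
            + "\n"
        )


#: within-group replicate noise (log2 sd), typical of biological microarray
#: replicates; distinct from the across-gene dynamic range _BASELINE_SD
_REPLICATE_SD = 0.25


def simulate_expression(
    n_genes: int,
    n_per_group: int,
    effect_log2fc: float,
    frac_deg: float,
    call_error_rate: float = 0.0,
    frac_down: float = 0.0,
    replicate_sd: float = _REPLICATE_SD,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Log-normal expression with a planted shift in group B for a gene subset.

    Per-gene baseline log2 levels are Normal(8, 1) across genes (the dynamic
    range); samples scatter around their gene's baseline with log2 sd
    ``replicate_sd``.  The first ``round(frac_deg * n_genes)`` genes carry the
    effect; a ``frac_down`` share of those is shifted down instead of up.
    Detection calls are "P" except flipped to "A" at ``call_error_rate``.
    """
    if not 0 < frac_deg < 1:
        raise SimulationError("frac_deg must lie in (0, 1)")
    if n_per_group < 2:
        raise SimulationError("need at least 2 samples per group")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:05d}" for i in range(n_genes)]
    samples = [f"ctrl{j}" for j in range(n_per_group)] + [f"case{j}" for j in range(n_per_group)]
    groups = {s: ("control" if s.startswith("ctrl") else "case") for s in samples}

    baseline = rng.normal(_BASELINE_LOG2, _BASELINE_SD, size=n_genes)
    log2 = baseline[:, None] + rng.normal(0.0, replicate_sd, size=(n_genes, 2 * n_per_group))
    n_deg = int(round(frac_deg * n_genes))
    n_down = int(round(frac_down * n_deg))
    effects = np.zeros(n_genes)
    effects[:n_deg] = effect_log2fc
    effects[:n_down] = -effect_log2fc
    log2[:, n_per_group:] += effects[:, None]

    signals = pd.DataFrame(2.0 ** log2, index=genes, columns=samples)
    calls_arr = np.where(rng.random((n_genes, 2 * n_per_group)) < call_error_rate, "A", "P")
    calls = pd.DataFrame(calls_arr, index=genes, columns=samples)

    truth = SyntheticTruth(seed=seed, planted_deg={genes[i]: float(effects[i]) for i in range(n_deg)})
    return ExpressionMatrix(signals=signals, detection_calls=calls, groups=groups), truth


def sample_site(pwm: PWM, rng: np.random.Generator, score_floor: float, max_tries: int = 2000) -> str:
    """Draw a site from the matrix conditioned on mss >= score_floor."""
    for _ in range(max_tries):
        idx = [int(rng.choice(4, p=row)) for row in pwm.freq]
        site = "".join(BASES[i] for i in idx)
        if match_score(pwm, site)[0] >= score_floor:
            return site
    raise SimulationError(f"could not sample a site from {pwm.id!r} with mss >= {score_floor}")


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


@dataclass(frozen=True)
class PlantingSpec:
    """How one matrix is planted: which genes, with what probability and floor."""

    genes: tuple[str, ...]
    probability: float = 1.0
    score_floor: float = 0.9


def simulate_promoters(
    genes: Sequence[str],
    pwm_library: Sequence[PWM],
    planting: Mapping[str, PlantingSpec] | None = None,
    length: int = PROMOTER_UPSTREAM + PROMOTER_DOWNSTREAM,
    gc: float = 0.45,
    max_span: int | None = None,
    seed: int = 0,
    fasta_path: str | Path | None = None,
    annotation_path: str | Path | None = None,
) -> tuple[list[PromoterRecord], SyntheticTruth]:
    """I.i.d.-background promoters with motif instances planted from PWMs.

    ``planting`` maps pwm id -> PlantingSpec; planted instances are sampled
    from the matrix conditioned on mss >= the requested floor and placed
    non-overlapping.  ``max_span`` confines all of a gene's planted sites to a
    window of that many bp (to honour composite-module distance constraints).
    Each gene gets its own contig; roughly half are placed on the minus strand
    so that extraction is exercised in both orientations.  Output files (when
    requested) are byte-deterministic for a fixed seed.
    """
    planting = dict(planting or {})
    by_id = {p.id: p for p in pwm_library}
    for pwm_id in planting:
        if pwm_id not in by_id:
            raise SimulationError(f"planting references unknown matrix {pwm_id!r}")
        if len(by_id[pwm_id]) >= length:
            raise SimulationError(f"matrix {pwm_id!r} longer than the promoter window")
    rng = np.random.default_rng(seed)
    records: list[PromoterRecord] = []
    truth = SyntheticTruth(seed=seed)
    ann_rows = []

    for gene in genes:
        codes = _random_background(rng, length, gc)
        occupied: list[tuple[int, int]] = []
        span_lo = 0
        span_hi = length
        for pwm_id, spec in planting.items():
            if gene not in spec.genes or rng.random() >= spec.probability:
                continue
            pwm = by_id[pwm_id]
            site = sample_site(pwm, rng, spec.score_floor)
            w = len(site)
            placed = False
            for _ in range(500):
                lo_bound = span_lo if max_span else 0
                hi_bound = (min(span_hi, length) - w) if max_span else (length - w)
                if hi_bound < lo_bound:
                    break
                off = int(rng.integers(lo_bound, hi_bound + 1))
                if any(off < e and off + w > s for s, e in occupied):
                    continue
                codes[off : off + w] = [BASES.index(b) for b in site]
                occupied.append((off, off + w))
                if max_span:
                    span_lo = max(span_lo, off + w - max_span)
                    span_hi = min(span_hi, off + max_span)
                truth.planted_motifs.append(
                    {"gene": gene, "pwm": pwm_id, "offset": off, "strand": "+", "site": site}
                )
                placed = True
                break
            if not placed:
                raise SimulationError(f"could not place site of {pwm_id!r} in {gene!r}")

        promoter = "".join(BASES[i] for i in codes)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            contig, tss = promoter, PROMOTER_UPSTREAM
        else:
            contig, tss = reverse_complement(promoter), PROMOTER_DOWNSTREAM
        records.append(PromoterRecord(gene_id=gene, chrom=f"chr_{gene}", strand=strand, tss=tss, seq=promoter))
        ann_rows.append((f"chr_{gene}", tss, strand, gene, contig))

    if fasta_path:
        with open(fasta_path, "w") as fh:
            for chrom, _, _, _, contig in ann_rows:
                fh.write(f">{chrom}\n")
                for i in range(0, len(contig), 70):
                    fh.write(contig[i : i + 70] + "\n")
    if annotation_path:
        pd.DataFrame(
            [(c, t, s, g) for c, t, s, g, _ in ann_rows], columns=["chrom", "tss", "strand", "gene_id"]
        ).to_csv(annotation_path, sep="\t", header=False, index=False)
    return records, truth


def simulate_pwm_library(
    n_matrices: int,
    length_range: tuple[int, int] = (6, 12),
    sharpness: float = 20.0,
    include_ebox: bool = True,
    seed: int = 0,
    path: str | Path | None = None,
) -> list[PWM]:
    """Random sharp matrices in JASPAR layout, optionally led by an E-box matrix.

    Each matrix is a Dirichlet draw per position concentrated on one consensus
    base (``sharpness`` controls how concentrated).  The E-box matrix models
    the canonical CACGTG with mild degeneracy at the two central positions.
    """
    rng = np.random.default_rng(seed)
    entries: list[tuple[str, str, np.ndarray]] = []
    if include_ebox:
        counts = []
        for i, base in enumerate("CACGTG"):
            row = np.full(4, 1.0)
            row[BASES.index(base)] = 40.0
            if i in (2, 3):  # central CG tolerates E-box-like variants
                row += 2.0
            counts.append(row)
        entries.append(("M_MYC", "Myc", np.array(counts)))
    while len(entries) < n_matrices:
        idx = len(entries)
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        counts = np.empty((L, 4))
        for i in range(L):
            alpha = np.ones(4)
            alpha[rng.integers(0, 4)] = sharpness
            counts[i] = np.round(rng.dirichlet(alpha) * 100) + 1
        entries.append((f"M_{idx:03d}", f"TF{idx:03d}", counts))

    if path:
        with open(path, "w") as fh:
            for mid, name, counts in entries:
                fh.write(f">{mid} {name}\n")
                for bi, base in enumerate(BASES):
                    vals = " ".join(f"{int(v):d}" for v in counts[:, bi])
                    fh.write(f"{base} [ {vals} ]\n")

    pwms = []
    for mid, name, counts in entries:
        c = counts + 0.01
        pwms.append(PWM(id=mid, tf_name=name, freq=c / c.sum(axis=1, keepdims=True)))
    return pwms


def simulate_network(
    n_nodes: int,
    mean_out_degree: float,
    input_genes: Sequence[str],
    wired_fraction: float = 0.0,
    wiring_distance: int = 1,
    hub: str = "HUB",
    seed: int = 0,
    path: str | Path | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Random directed graph plus a planted hub wired to part of the input set.

    Background out-degrees are Poisson around ``mean_out_degree`` with uniform
    targets; edge types are drawn uniformly.  The hub gets paths of exactly
    ``wiring_distance`` edges (through fresh connector nodes when > 1) to
    ``round(wired_fraction * |inputs|)`` inputs.
    """
    inputs = list(dict.fromkeys(input_genes))
    if n_nodes <= len(inputs):
        raise SimulationError("n_nodes must exceed the input-set size")
    n_wired = int(round(wired_fraction * len(inputs)))
    if n_wired > len(inputs) or wiring_distance < 1:
        raise SimulationError("requested wiring infeasible")
    rng = np.random.default_rng(seed)

    others = [f"n{i:04d}" for i in range(n_nodes - len(inputs) - 1)]
    nodes = inputs + [hub] + others
    types = np.array(["activation", "inhibition", "regulation"])
    rows: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str]] = set()

    def add_edge(src: str, tgt: str) -> None:
        if src != tgt and (src, tgt) not in seen:
            seen.add((src, tgt))
            rows.append((src, tgt, str(rng.choice(types))))

    for src in nodes:
        if src == hub:  # the hub's out-edges are exactly the planted wiring
            continue
        for _ in range(rng.poisson(mean_out_degree)):
            add_edge(src, str(rng.choice(nodes)))

    wired = inputs[:n_wired]
    for i, gene in enumerate(wired):
        prev = hub
        for step in range(wiring_distance - 1):
            connector = f"c_{i}_{step}"
            add_edge(prev, connector)
            prev = connector
        add_edge(prev, gene)

    df = pd.DataFrame(rows, columns=["source", "target", "type"])
    if path:
        df.to_csv(path, sep="\t", header=False, index=False)
    truth = SyntheticTruth(
        seed=seed,
        planted_regulator={"hub": hub, "wired_inputs": wired, "distance": wiring_distance},
    )
    return df, truth
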