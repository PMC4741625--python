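"""Promoter extraction and MATCH-style position-weight-matrix scanning.

A PWM is a per-position base-frequency model of a transcription-factor binding
motif.  Scoring follows the information-vector scheme: each position i carries
a conservation weight

    I(i) = sum_b f(i,b) * ln(4 * f(i,b))        (0*ln 0 := 0),

and a candidate window b_1..b_L scores

    Current = sum_i I(i) * f(i, b_i),
    mss = (Current - Min) / (Max - Min),

where Min and Max are the lowest and highest achievable Current.  The core
similarity (css) is the same quantity restricted to the five consecutive most
informative positions.  A window is a hit when css >= core_cutoff and
mss >= matrix_cutoff; both strands are scanned and minus-strand hits are
reported at their plus-strand start offset.

Promoters are the window -1000..+100 around the annotated TSS (1100 bp under
the defaults), reverse-complemented for minus-strand genes, N-padded past
contig ends.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_CORE_CUTOFF = 0.75
DEFAULT_MATRIX_CUTOFF = 0.80
CORE_LENGTH = 5
MAX_N_FRACTION = 0.2


class PWMError(ValueError):
    """Raised for malformed matrices or scan inputs."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """Normalized frequency matrix with derived information vector and core.

    ``freq`` has shape (length, 4) in A,C,G,T order; rows sum to 1.  The core
    is the 5-position window maximizing summed information (leftmost on ties).
    """

    id: str
    tf_name: str
    freq: np.ndarray
    pseudocount: float = 0.01
    core_cutoff: float = DEFAULT_CORE_CUTOFF
    matrix_cutoff: float = DEFAULT_MATRIX_CUTOFF
    info_vector: np.ndarray = field(init=False)
    core_start: int = field(init=False)

    def __post_init__(self) -> None:
        f = np.asarray(self.freq, dtype=float)
        if f.ndim != 2 or f.shape[1] != 4:
            raise PWMError(f"matrix {self.id!r}: frequency array must be L x 4")
        if f.shape[0] < CORE_LENGTH:
            raise PWMError(f"matrix {self.id!r}: length {f.shape[0]} < {CORE_LENGTH}")
        if not np.allclose(f.sum(axis=1), 1.0, atol=1e-9):
            raise PWMError(f"matrix {self.id!r}: position frequencies do not sum to 1")
        self.freq = f
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(f > 0, f * np.log(4.0 * f), 0.0)
        self.info_vector = terms.sum(axis=1)
        window_info = np.convolve(self.info_vector, np.ones(CORE_LENGTH), mode="valid")
        self.core_start = int(np.argmax(window_info))  # argmax -> leftmost tie

    def __len__(self) -> int:
        return self.freq.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.freq.argmax(axis=1))

    def _weight_table(self, positions: slice) -> tuple[np.ndarray, float, float]:
        """Per-base weighted contributions plus Min/Max over the given positions.

        Returns a (L, 5) table where column 4 is the N contribution (the
        position's minimal frequency, the conservative choice).
        """
        f = self.freq[positions]
        iv = self.info_vector[positions][:, None]
        table = np.empty((f.shape[0], 5))
        table[:, :4] = iv * f
        table[:, 4] = (iv * f.min(axis=1, keepdims=True))[:, 0]
        return table, float(table[:, :4].min(axis=1).sum()), float(table[:, :4].max(axis=1).sum())


@dataclass(frozen=True)
class PromoterRecord:
    """Uppercased promoter sequence with its genomic anchor."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    seq: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise PWMError(f"gene {self.gene_id!r}: malformed strand {self.strand!r}")
        bad = set(self.seq) - set("ACGTN")
        if bad:
            raise PWMError(f"gene {self.gene_id!r}: unexpected characters {sorted(bad)}")


@dataclass(frozen=True)
class SiteHit:
    gene_id: str
    pwm_id: str
    offset: int
    strand: str
    mss: float
    css: float


@dataclass
class GeneSets:
    """Foreground (regulated) vs background (unregulated, Myc-site-free) genes."""

    yes_set: set[str]
    no_set: set[str]

    def __post_init__(self) -> None:
        if self.yes_set & self.no_set:
            raise PWMError("YES and NO sets overlap")


def load_pwms(
    path: str | Path,
    pseudocount: float = 0.01,
    core_cutoff: float = DEFAULT_CORE_CUTOFF,
    matrix_cutoff: float = DEFAULT_MATRIX_CUTOFF,
    cutoffs: Mapping[str, tuple[float, float]] | None = None,
) -> list[PWM]:
    """Read a JASPAR-style matrix file into normalized PWMs.

    Counts (or frequencies) get ``pseudocount`` added per cell before
    per-position normalization.  ``cutoffs`` optionally overrides
    (core_cutoff, matrix_cutoff) per matrix id.
    """
    with open(path) as handle:
        records = bio_motifs.parse(handle, "jaspar")
    pwms = []
    for rec in records:
        counts = np.array([rec.counts[b] for b in BASES], dtype=float).T
        col_sums = counts.sum(axis=1)
        if np.any(col_sums <= 0):
            raise PWMError(f"matrix {rec.matrix_id!r}: position with zero total count")
        counts = counts + pseudocount
        freq = counts / counts.sum(axis=1, keepdims=True)
        cc, mc = (cutoffs or {}).get(rec.matrix_id, (core_cutoff, matrix_cutoff))
        pwms.append(
            PWM(
                id=rec.matrix_id,
                tf_name=rec.name or rec.matrix_id,
                freq=freq,
                pseudocount=pseudocount,
                core_cutoff=cc,
                matrix_cutoff=mc,
            )
        )
    if not pwms:
        raise PWMError(f"no matrices parsed from {path}")
    return pwms


def calibrate_matrix_cutoff(
    pwm: PWM,
    p_value: float = 1e-4,
    gc: float = 0.5,
    n_samples: int = 50000,
    seed: int = 0,
) -> float:
    """Per-matrix mss cutoff at a target per-window false-positive rate.

    Mirrors the stringent per-matrix cutoff profiles used with MATCH-style
    scanners: the cutoff is the (1 - p_value) quantile of the mss null
    distribution over i.i.d. background windows at the given GC content,
    estimated by sampling (deterministic for a fixed seed).  Fixed cutoffs
    like the 0.80 default behave very differently across matrix lengths;
    calibration equalizes specificity.
    """
    rng = np.random.default_rng(seed)
    L = len(pwm)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=(n_samples, L), p=probs)
    table, lo, hi = pwm._weight_table(slice(None))
    cur = np.zeros(n_samples)
    for i in range(L):
        cur += table[i, codes[:, i]]
    if hi == lo:
        return 1.0
    mss = (cur - lo) / (hi - lo)
    return float(min(np.quantile(mss, 1 - p_value), 1.0))


def _encode(seq: str) -> np.ndarray:
    """Map A,C,G,T,N -> 0..4."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def match_score(pwm: PWM, window: str) -> tuple[float, float]:
    """(mss, css) of a single window of exactly the matrix length."""
    if len(window) != len(pwm):
        raise PWMError(f"window length {len(window)} != matrix length {len(pwm)}")
    codes = _encode(window.upper())
    mss = _score_one(pwm, codes, slice(None))
    css = _score_one(pwm, codes, slice(pwm.core_start, pwm.core_start + CORE_LENGTH))
    return mss, css


def _score_one(pwm: PWM, codes: np.ndarray, positions: slice) -> float:
    table, lo, hi = pwm._weight_table(positions)
    current = float(table[np.arange(table.shape[0]), codes[positions]].sum())
    if hi == lo:
        return 1.0
    return (current - lo) / (hi - lo)


def _scan_strand(pwm: PWM, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized mss/css for every window start on one strand."""
    L, W = len(codes), len(pwm)
    n_win = L - W + 1
    if n_win <= 0:
        return np.empty(0), np.empty(0)
    full, f_lo, f_hi = pwm._weight_table(slice(None))
    core_sl = slice(pwm.core_start, pwm.core_start + CORE_LENGTH)
    core, c_lo, c_hi = pwm._weight_table(core_sl)

    windows = np.lib.stride_tricks.sliding_window_view(codes, W)  # (n_win, W)
    # gather contributions position by position (W is small)
    cur_full = np.zeros(n_win)
    for i in range(W):
        cur_full += full[i, windows[:, i]]
    cur_core = np.zeros(n_win)
    for j, i in enumerate(range(core_sl.start, core_sl.stop)):
        cur_core += core[j, windows[:, i]]

    mss = np.ones(n_win) if f_hi == f_lo else (cur_full - f_lo) / (f_hi - f_lo)
    css = np.ones(n_win) if c_hi == c_lo else (cur_core - c_lo) / (c_hi - c_lo)
    # skip N-heavy windows
    n_frac = np.zeros(n_win)
    is_n = (codes == 4).astype(float)
    if is_n.any():
        n_frac = np.convolve(is_n, np.ones(W), mode="valid") / W
    keep = n_frac <= MAX_N_FRACTION
    mss[~keep] = -1.0
    css[~keep] = -1.0
    return mss, css


def scan_sequence(pwm: PWM, seq: str) -> list[tuple[int, str, float, float]]:
    """All supra-cutoff matches of one matrix in one sequence, both strands.

    Returns (plus-strand offset of match start, strand, mss, css) tuples.
    """
    seq = seq.upper()
    W = len(pwm)
    hits: list[tuple[int, str, float, float]] = []
    fwd = _encode(seq)
    mss, css = _scan_strand(pwm, fwd)
    for off in np.nonzero((mss >= pwm.matrix_cutoff) & (css >= pwm.core_cutoff))[0]:
        hits.append((int(off), "+", float(mss[off]), float(css[off])))
    rev = _encode(reverse_complement(seq))
    mss, css = _scan_strand(pwm, rev)
    L = len(seq)
    for off in np.nonzero((mss >= pwm.matrix_cutoff) & (css >= pwm.core_cutoff))[0]:
        plus_off = L - W - int(off)
        hits.append((plus_off, "-", float(mss[off]), float(css[off])))
    hits.sort()
    return hits


def extract_promoters(
    genome_path: str | Path,
    annotation_path: str | Path,
    upstream: int = 1000,
    downstream: int = 100,
) -> list[PromoterRecord]:
    """Cut promoter windows around annotated TSSs from a FASTA genome.

    The annotation is a headerless BED-like TSV (chrom, tss, strand, gene_id)
    with 0-based TSS coordinates.  Plus strand yields [tss-upstream,
    tss+downstream); minus strand the reverse complement of [tss-downstream,
    tss+upstream).  Windows running off a contig are N-padded to full length.
    """
    from pyfaidx import Fasta

    genome = Fasta(str(genome_path), sequence_always_upper=True)
    ann = pd.read_csv(
        annotation_path,
        sep="\t",
        header=None,
        names=["chrom", "tss", "strand", "gene_id"],
        dtype={"chrom": str, "tss": int, "strand": str, "gene_id": str},
        comment="#",
    )
    records = []
    for row in ann.itertuples(index=False):
        if row.strand not in {"+", "-"}:
            raise PWMError(f"gene {row.gene_id!r}: malformed strand {row.strand!r}")
        if row.chrom not in genome:
            warnings.warn(f"gene {row.gene_id!r}: unknown chromosome {row.chrom!r}, skipped", stacklevel=2)
            continue
        contig_len = len(genome[row.chrom])
        if row.strand == "+":
            start, end = row.tss - upstream, row.tss + downstream
        else:
            start, end = row.tss - downstream, row.tss + upstream
        lo, hi = max(start, 0), min(end, contig_len)
        core = str(genome[row.chrom][lo:hi]) if hi > lo else ""
        seq = "N" * (lo - start) + core + "N" * (end - hi)
        if row.strand == "-":
            seq = reverse_complement(seq)
        records.append(
            PromoterRecord(gene_id=row.gene_id, chrom=row.chrom, strand=row.strand, tss=row.tss, seq=seq)
        )
    return records


def scan_promoters(pwms: Sequence[PWM], promoters: Sequence[PromoterRecord]) -> list[SiteHit]:
    """Scan every promoter with every matrix; collect all supra-cutoff hits."""
    hits: list[SiteHit] = []
    for prom in promoters:
        for pwm in pwms:
            if len(prom.seq) < len(pwm):
                warnings.warn(
                    f"gene {prom.gene_id!r}: promoter shorter than matrix {pwm.id!r}, skipped",
                    stacklevel=2,
                )
                continue
            for off, strand, mss, css in scan_sequence(pwm, prom.seq):
                hits.append(SiteHit(prom.gene_id, pwm.id, off, strand, mss, css))
    return hits


def hits_table(hits: Sequence[SiteHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.gene_id, h.pwm_id, h.offset, h.strand, h.mss, h.css) for h in hits],
        columns=["gene_id", "pwm_id", "offset", "strand", "mss", "css"],
    )


def genes_with_hits(hits: Iterable[SiteHit], pwm_ids: Iterable[str] | None = None) -> set[str]:
    """Genes carrying >= 1 hit, optionally restricted to the given matrices."""
    wanted = set(pwm_ids) if pwm_ids is not None else None
    return {h.gene_id for h in hits if wanted is None or h.pwm_id in wanted}


def build_gene_sets(
    all_genes: Iterable[str],
    yes_genes: Iterable[str],
    background_regulated: Iterable[str],
    myc_pwm_ids: Iterable[str],
    hits: Sequence[SiteHit],
) -> GeneSets:
    """Assemble the YES (regulated) and NO (background) gene sets.

    The NO set is everything that is neither a YES gene, nor flagged regulated
    under the relaxed background filter, nor a carrier of any Myc-matrix hit.
    """
    all_set = set(all_genes)
    yes = set(yes_genes) & all_set
    myc_carriers = genes_with_hits(hits, myc_pwm_ids)
    no = all_set - yes - set(background_regulated) - myc_carriers
    if not no:
        raise PWMError("background exhausted: every candidate gene is regulated or carries a Myc site")
    return GeneSets(yes_set=yes, no_set=no)


def matrix_enrichment(
    pwms: Sequence[PWM],
    hits: Sequence[SiteHit],
    yes_set: set[str],
    no_set: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-matrix over-representation of hit-bearing genes in YES vs NO.

    One-sided Fisher exact test on the 2x2 gene-level presence table, with
    Benjamini-Hochberg adjustment across matrices.
    """
    if not yes_set:
        raise PWMError("empty YES set")
    if not no_set:
        raise PWMError("empty NO set")
    rows = []
    for pwm in pwms:
        carriers = genes_with_hits(hits, [pwm.id])
        a = len(carriers & yes_set)
        b = len(yes_set) - a
        c = len(carriers & no_set)
        d = len(no_set) - c
        p = float(stats.fisher_exact([[a, b], [c, d]], alternative="greater").pvalue)
        rows.append((pwm.id, pwm.tf_name, a, len(yes_set), c, len(no_set), p))
    df = pd.DataFrame(
        rows, columns=["pwm_id", "tf_name", "yes_present", "yes_total", "no_present", "no_total", "p_value"]
    )
    df["fdr_q"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df["enriched"] = df["p_value"] <= alpha
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)
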