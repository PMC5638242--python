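"""TF-gene regulatory network from open-chromatin peaks.

The regulatory layer licenses a TF->gene edge when a significant match to the
TF's position weight matrix (PWM) falls inside an accessible-chromatin peak
whose match midpoint lies within a fixed window (default 5 kb) of the gene's
transcription start site. Edge weight is the best normalized match score, so
weights live in (0, 1] and can be read as interaction confidences downstream.

Scoring follows the MATCH convention: the log-odds of a window under the PWM
(uniform background) is min-max normalized per matrix, and matches are kept
when the normalized score reaches the matrix's own threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .exceptions import InputError

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = np.array([3, 2, 1, 0])
_PROB_EPS = 1e-9

DEFAULT_PWM_THRESHOLD = 0.85
DEFAULT_TSS_WINDOW = 5000


@dataclass
class PWM:
    """Position probability matrix for one TF with a per-matrix score threshold."""

    tf: str
    matrix: np.ndarray  # shape (L, 4), rows sum to 1
    threshold: float = DEFAULT_PWM_THRESHOLD

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise InputError(f"PWM {self.tf}: matrix must be L x 4")
        if len(self) < 4:
            raise InputError(f"PWM {self.tf}: length {len(self)} < 4")
        sums = self.matrix.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > 1e-6)[0]
        if bad.size:
            raise InputError(
                f"PWM {self.tf}: probabilities at position {bad[0] + 1} sum to {sums[bad[0]]:.4g}"
            )

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        # uniform background; epsilon keeps zero-probability cells finite
        return np.log(self.matrix + _PROB_EPS) - np.log(0.25)


@dataclass
class MotifMatch:
    tf: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str
    score: float


def read_transfac_pwms(path, default_threshold: float = DEFAULT_PWM_THRESHOLD) -> list[PWM]:
    """Parse a TRANSFAC-style matrix file (Bio.motifs); thresholds ride in CC records."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        records = bio_motifs.parse(fh, "TRANSFAC")
    pwms = []
    for rec in records:
        counts = np.array([rec.counts[b] for b in ALPHABET], dtype=float).T
        if counts.size and counts.max() <= 1.0:
            # probability-style matrix: keep as-is so PWM validates row sums
            matrix = counts
        else:
            sums = counts.sum(axis=1, keepdims=True)
            zero = np.where(sums[:, 0] <= 0)[0]
            if zero.size:
                raise InputError(
                    f"PWM {rec['ID']}: counts at position {zero[0] + 1} sum to zero"
                )
            matrix = counts / sums
        threshold = default_threshold
        for cc in rec.get("CC", []) or []:
            if cc.strip().lower().startswith("threshold:"):
                threshold = float(cc.split(":", 1)[1])
        pwms.append(PWM(tf=rec["ID"].upper(), matrix=matrix, threshold=threshold))
    return pwms


def write_transfac_pwms(pwms: list[PWM], path, counts_scale: int = 100) -> None:
    from Bio import motifs as bio_motifs
    from Bio.motifs import transfac

    records = []
    for pwm in pwms:
        counts = {
            b: list(np.round(pwm.matrix[:, i] * counts_scale, 4)) for i, b in enumerate(ALPHABET)
        }
        m = transfac.Motif(alphabet="ACGT", counts=counts)
        m["ID"] = pwm.tf
        m["CC"] = [f"threshold: {pwm.threshold}"]
        records.append(m)
    with open(path, "w") as fh:
        fh.write(bio_motifs.write(records, "transfac"))


# ---------------------------------------------------------------------------
# peak handling


def merge_peak_sets(peak_sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Union of interval sets; overlapping or bookended intervals are merged.

    Returns a (chrom, start, end) frame sorted by (chrom, start). Idempotent
    and invariant to the order of the input sets.
    """
    frames = [p[["chrom", "start", "end"]] for p in peak_sets if len(p)]
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    allp = pd.concat(frames, ignore_index=True)
    allp = allp.sort_values(["chrom", "start", "end"], kind="mergesort")
    out = []
    for chrom, grp in allp.groupby("chrom", sort=True):
        cur_start = cur_end = None
        for start, end in zip(grp["start"], grp["end"]):
            if cur_start is None:
                cur_start, cur_end = start, end
            elif start <= cur_end:  # overlap or bookend
                cur_end = max(cur_end, end)
            else:
                out.append((chrom, cur_start, cur_end))
                cur_start, cur_end = start, end
        out.append((chrom, cur_start, cur_end))
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _scan_encoded(enc: np.ndarray, pwm: PWM) -> tuple[np.ndarray, np.ndarray]:
    """Normalized scores of every window on + and - strands; NaN where ambiguous."""
    L = len(pwm)
    n_win = enc.size - L + 1
    if n_win <= 0:
        return np.empty(0), np.empty(0)
    lo = pwm.log_odds()
    lo_rc = lo[::-1, _COMPLEMENT]  # scoring the reverse complement in place
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    valid = (windows >= 0).all(axis=1)
    pos = np.arange(L)
    safe = np.where(windows >= 0, windows, 0)
    raw_fwd = lo[pos, safe].sum(axis=1)
    raw_rev = lo_rc[pos, safe].sum(axis=1)
    mn, mx = lo.min(axis=1).sum(), lo.max(axis=1).sum()
    span = mx - mn if mx > mn else 1.0
    fwd = np.where(valid, (raw_fwd - mn) / span, np.nan)
    rev = np.where(valid, (raw_rev - mn) / span, np.nan)
    return fwd, rev


def scan_motifs(
    genome: dict[str, str], peaks: pd.DataFrame, pwms: list[PWM]
) -> list[MotifMatch]:
    """Scan both strands of every peak with every PWM.

    Peaks reaching past a chromosome end are clipped with a warning. A window
    containing an ambiguous base never matches.
    """
    matches: list[MotifMatch] = []
    for _, peak in peaks.iterrows():
        chrom = peak["chrom"]
        if chrom not in genome:
            warnings.warn(f"peak on unknown sequence {chrom!r}; skipped")
            continue
        chrom_len = len(genome[chrom])
        start, end = int(peak["start"]), int(peak["end"])
        if end > chrom_len:
            warnings.warn(f"peak [{start}, {end}) clipped to {chrom} length {chrom_len}")
            end = chrom_len
        if start >= end:
            continue
        enc = _encode(genome[chrom][start:end])
        for pwm in pwms:
            fwd, rev = _scan_encoded(enc, pwm)
            for strand, scores in (("+", fwd), ("-", rev)):
                idx = np.where(scores >= pwm.threshold)[0]
                for i in idx:
                    matches.append(
                        MotifMatch(
                            tf=pwm.tf,
                            chrom=chrom,
                            start=start + int(i),
                            end=start + int(i) + len(pwm),
                            strand=strand,
                            score=float(scores[i]),
                        )
                    )
    return matches


def matches_to_frame(matches: list[MotifMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        [(m.tf, m.chrom, m.start, m.end, m.strand, m.score) for m in matches],
        columns=["tf", "chrom", "start", "end", "strand", "score"],
    )


def build_tf_gene_network(
    matches: list[MotifMatch] | pd.DataFrame,
    tss: pd.DataFrame,
    window: int = DEFAULT_TSS_WINDOW,
) -> pd.DataFrame:
    """TF->gene edges: best match score with midpoint within +/- window of the TSS.

    A single match may support several genes; the gene's own strand does not
    restrict which matches count.
    """
    mdf = matches if isinstance(matches, pd.DataFrame) else matches_to_frame(matches)
    if mdf.empty or tss.empty:
        return pd.DataFrame(columns=["tf", "gene", "weight"])
    mdf = mdf.assign(mid=(mdf["start"] + mdf["end"]) / 2.0)
    edges = {}
    for chrom, grp in mdf.groupby("chrom"):
        genes = tss[tss["chrom"] == chrom]
        if genes.empty:
            continue
        order = np.argsort(genes["tss"].to_numpy())
        tss_pos = genes["tss"].to_numpy()[order]
        gene_names = genes["gene"].to_numpy()[order]
        mids = grp["mid"].to_numpy()
        lo = np.searchsorted(tss_pos, mids - window, side="left")
        hi = np.searchsorted(tss_pos, mids + window, side="right")
        for (tf, score), l, h in zip(zip(grp["tf"], grp["score"]), lo, hi):
            for g in gene_names[l:h]:
                key = (tf, g)
                if score > edges.get(key, 0.0):
                    edges[key] = score
    out = pd.DataFrame(
        [(tf, g, w) for (tf, g), w in edges.items()], columns=["tf", "gene", "weight"]
    )
    return out.sort_values(["tf", "gene"], ignore_index=True)


def tf_enrichment(
    regulatory_edges: pd.DataFrame,
    de_genes: set[str],
    background_genes: set[str],
    min_de_promoters: int = 100,
) -> pd.DataFrame:
    """Per-TF one-sided Fisher exact test for motif overrepresentation.

    The 2x2 table contrasts DE vs non-DE genes (within the supplied background
    of peak-bearing promoters) by presence of the TF's motif. TFs whose motif
    hits fewer than ``min_de_promoters`` DE promoters are reported but flagged.
    """
    de = set(de_genes) & set(background_genes)
    non_de = set(background_genes) - de
    if not de:
        return pd.DataFrame(
            columns=["tf", "n_de_with_motif", "odds_ratio", "p_value", "flagged"]
        )
    rows = []
    for tf, grp in regulatory_edges.groupby("tf"):
        targets = set(grp["gene"]) & set(background_genes)
        a = len(targets & de)
        b = len(de) - a
        c = len(targets & non_de)
        d = len(non_de) - c
        odds, p = fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((tf, a, odds, p, a < min_de_promoters))
    out = pd.DataFrame(
        rows, columns=["tf", "n_de_with_motif", "odds_ratio", "p_value", "flagged"]
    )
    return out.sort_values("p_value", ignore_index=True)
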