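"""Bootstrap significance analysis of APA (SAAP) and its depth-controlled
global counterpart (GAAP).

SAAP: for one gene with proximal/distal read counts in two samples, the
observed RED is compared against resamples drawn under the null that the
isoform proportions are identical in both samples (binomial draws with
the pooled proximal fraction, preserving each sample's total).  The
observed RED is standardised by the resample mean and SD into a Z score
(Zo); a matched null Z (Ze) per gene, obtained by running the same
procedure on a pooled-proportion resample of the counts, yields an
empirical FDR for any |Z| cutoff:  FDR(Zc) = #{|Ze|>=Zc} / #{|Zo|>=Zc}.

GAAP: to compare the extent of APA regulation between sample pairs at
equal sequencing depth, a fixed number of reads is bootstrapped from
each sample, SAAP counts the significant genes (observed), the two
samples' reads are pooled and split at random into two pseudo-samples of
the same depth to get the no-regulation count (expected), and the
normalised count is observed - expected, with an SD over repeats.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

COUNT_COLS = ["a_prx", "a_dis", "b_prx", "b_dis"]


@dataclass
class ApaTestResult:
    gene_id: str
    red_obs: float
    boot_mean: float
    boot_sd: float
    z: float  # NaN when boot_sd == 0
    z_expected: float
    fdr_class: str = "unchanged"


@dataclass
class GaapResult:
    comparison: str
    depth: int
    observed_count: float
    expected_count: float
    normalized_count: float
    sd: float
    sh: float
    le: float
    log2_sh_le: float


def _re(prx: np.ndarray, dis: np.ndarray) -> np.ndarray:
    """log2(dis/prx) with a 0.5-read pseudocount where either count is 0."""
    prx = np.asarray(prx, float)
    dis = np.asarray(dis, float)
    ps = np.where((prx == 0) | (dis == 0), 0.5, 0.0)
    return np.log2((dis + ps) / (prx + ps))


def saap_z(
    a_prx: int,
    a_dis: int,
    b_prx: int,
    b_dis: int,
    n_boot: int = 20,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, float, float]:
    """(red_obs, boot_mean, boot_sd, z) for one gene; z is NaN if sd = 0."""
    out = saap_table(
        pd.DataFrame([[a_prx, a_dis, b_prx, b_dis]], columns=COUNT_COLS),
        n_boot=n_boot,
        seed=seed,
    )
    r = out.iloc[0]
    return float(r.red_obs), float(r.boot_mean), float(r.boot_sd), float(r.z)


def saap_table(
    counts: pd.DataFrame,
    n_boot: int = 20,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Vectorised SAAP Z computation over a gene x counts table.

    ``counts`` must carry columns a_prx, a_dis, b_prx, b_dis; both
    per-sample totals must be positive for every gene.  The SD from the
    default 20 resamples is noisy; >=200 is recommended when runtime
    allows.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a_prx = counts["a_prx"].to_numpy(int)
    a_dis = counts["a_dis"].to_numpy(int)
    b_prx = counts["b_prx"].to_numpy(int)
    b_dis = counts["b_dis"].to_numpy(int)
    n_a = a_prx + a_dis
    n_b = b_prx + b_dis
    if (n_a <= 0).any() or (n_b <= 0).any():
        raise ValueError("every gene needs >0 reads in both samples")

    red_obs = _re(b_prx, b_dis) - _re(a_prx, a_dis)
    p_hat = (a_prx + b_prx) / (n_a + n_b)  # pooled proximal fraction

    g = len(counts)
    ap = rng.binomial(n_a[:, None], p_hat[:, None], size=(g, n_boot))
    bp = rng.binomial(n_b[:, None], p_hat[:, None], size=(g, n_boot))
    red_null = _re(bp, n_b[:, None] - bp) - _re(ap, n_a[:, None] - ap)
    mean = red_null.mean(axis=1)
    sd = red_null.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (red_obs - mean) / sd, np.nan)
    return pd.DataFrame(
        {"red_obs": red_obs, "boot_mean": mean, "boot_sd": sd, "z": z},
        index=counts.index,
    )


def null_resample(
    counts: pd.DataFrame, seed: int | np.random.Generator = 0
) -> pd.DataFrame:
    """A pooled-proportion resample of the counts (per-sample totals kept)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a_prx = counts["a_prx"].to_numpy(int)
    b_prx = counts["b_prx"].to_numpy(int)
    n_a = a_prx + counts["a_dis"].to_numpy(int)
    n_b = b_prx + counts["b_dis"].to_numpy(int)
    p_hat = (a_prx + b_prx) / (n_a + n_b)
    ap = rng.binomial(n_a, p_hat)
    bp = rng.binomial(n_b, p_hat)
    return pd.DataFrame(
        {"a_prx": ap, "a_dis": n_a - ap, "b_prx": bp, "b_dis": n_b - bp},
        index=counts.index,
    )


def saap_fdr(
    z_observed: np.ndarray,
    z_null: np.ndarray,
    fdr_target: float = 0.05,
    zc_grid: Optional[np.ndarray] = None,
) -> tuple[Optional[float], np.ndarray, float]:
    """Pick the smallest |Z| cutoff whose empirical FDR meets the target.

    Genes with undefined Z (NaN) are excluded from both lists.  Returns
    (Zc or None, boolean significant mask over the input genes, achieved
    FDR at Zc); the mask is all-False when no cutoff reaches the target.
    """
    z_observed = np.asarray(z_observed, float)
    z_null = np.asarray(z_null, float)
    if zc_grid is None:
        zc_grid = np.arange(0.0, 10.01, 0.1)
    zo = np.abs(z_observed[~np.isnan(z_observed)])
    ze = np.abs(z_null[~np.isnan(z_null)])
    for zc in zc_grid:
        n_obs = int((zo >= zc).sum())
        n_null = int((ze >= zc).sum())
        fdr = n_null / max(1, n_obs)
        if fdr <= fdr_target and n_obs > 0:
            mask = np.abs(np.nan_to_num(z_observed, nan=-np.inf)) >= zc
            return float(zc), mask, fdr
    return None, np.zeros(len(z_observed), dtype=bool), 1.0


def classify_direction(
    red_obs: np.ndarray, significant: np.ndarray
) -> tuple[int, int, float]:
    """(Sh#, Le#, log2(Sh#/Le#)) of significant genes by the RED sign."""
    red_obs = np.asarray(red_obs, float)
    significant = np.asarray(significant, bool)
    sh = int(((red_obs < 0) & significant).sum())
    le = int(((red_obs > 0) & significant).sum())
    ps = 0.5 if (sh == 0 or le == 0) else 0.0
    ratio = float(np.log2((sh + ps) / (le + ps)))
    return sh, le, ratio


def saap_analysis(
    counts: pd.DataFrame,
    n_boot: int = 20,
    fdr_target: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, dict]:
    """Full per-gene SAAP: Zo, matched Ze, FDR cutoff, direction classes.

    Returns the per-gene result table (red_obs, z, z_expected,
    significant, fdr_class) and a summary dict (zc, fdr, sh, le,
    log2_sh_le, n_undefined).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    obs = saap_table(counts, n_boot=n_boot, seed=rng)
    ze = saap_table(null_resample(counts, seed=rng), n_boot=n_boot, seed=rng)
    zc, mask, fdr = saap_fdr(obs["z"].to_numpy(), ze["z"].to_numpy(), fdr_target)
    sh, le, ratio = classify_direction(obs["red_obs"].to_numpy(), mask)
    out = obs.copy()
    out["z_expected"] = ze["z"]
    out["significant"] = mask
    cls = np.where(
        mask & (out["red_obs"] < 0),
        "shortened",
        np.where(mask & (out["red_obs"] > 0), "lengthened", "unchanged"),
    )
    out["fdr_class"] = cls
    summary = {
        "zc": zc,
        "fdr": fdr,
        "sh": sh,
        "le": le,
        "log2_sh_le": ratio,
        "n_undefined": int(obs["z"].isna().sum()),
    }
    return out, summary


# ---------------------------------------------------------------------------
# GAAP
# ---------------------------------------------------------------------------

def _bootstrap_side(
    prx: np.ndarray, dis: np.ndarray, depth: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Multinomially draw ``depth`` reads over the gene x isoform cells."""
    cells = np.concatenate([prx, dis]).astype(float)
    draw = rng.multinomial(depth, cells / cells.sum())
    g = len(prx)
    return draw[:g], draw[g:]


def gaap(
    counts: pd.DataFrame,
    depth: int = 1_500_000,
    n_rep: int = 20,
    n_boot: int = 20,
    fdr_target: float = 0.05,
    seed: int = 0,
    comparison: str = "A_vs_B",
) -> GaapResult:
    """Depth-controlled count of significantly regulated APA genes.

    Per repeat, ``depth`` reads are bootstrapped from each sample's
    gene x isoform counts and SAAP counts the significant genes
    (observed); the two sides are pooled and re-split into two random
    pseudo-samples of ``depth`` reads for the permutation expectation.
    Genes dropping to zero reads on either side within a repeat are
    excluded from that repeat's SAAP.
    """
    rng = np.random.default_rng(seed)
    a_prx = counts["a_prx"].to_numpy(int)
    a_dis = counts["a_dis"].to_numpy(int)
    b_prx = counts["b_prx"].to_numpy(int)
    b_dis = counts["b_dis"].to_numpy(int)
    for name, tot in (("A", a_prx.sum() + a_dis.sum()), ("B", b_prx.sum() + b_dis.sum())):
        if tot < depth:
            warnings.warn(
                f"sample {name} has {tot} reads < depth {depth}; lowering depth"
            )
            depth = int(min(depth, tot))

    pooled_prx = a_prx + b_prx
    pooled_dis = a_dis + b_dis
    obs_counts, exp_counts, sh_counts, le_counts = [], [], [], []
    for _ in range(n_rep):
        def run(prx_a, dis_a, prx_b, dis_b) -> tuple[int, int, int]:
            tab = pd.DataFrame(
                {"a_prx": prx_a, "a_dis": dis_a, "b_prx": prx_b, "b_dis": dis_b}
            )
            tab = tab[(tab.a_prx + tab.a_dis > 0) & (tab.b_prx + tab.b_dis > 0)]
            _, summary = saap_analysis(
                tab, n_boot=n_boot, fdr_target=fdr_target, seed=rng
            )
            return summary["sh"] + summary["le"], summary["sh"], summary["le"]

        pa, da = _bootstrap_side(a_prx, a_dis, depth, rng)
        pb, db = _bootstrap_side(b_prx, b_dis, depth, rng)
        n_sig, sh, le = run(pa, da, pb, db)
        obs_counts.append(n_sig)
        sh_counts.append(sh)
        le_counts.append(le)

        pa, da = _bootstrap_side(pooled_prx, pooled_dis, depth, rng)
        pb, db = _bootstrap_side(pooled_prx, pooled_dis, depth, rng)
        n_sig, _, _ = run(pa, da, pb, db)
        exp_counts.append(n_sig)

    obs_arr = np.array(obs_counts, float)
    exp_arr = np.array(exp_counts, float)
    sh_mean = float(np.mean(sh_counts))
    le_mean = float(np.mean(le_counts))
    ps = 0.5 if (sh_mean == 0 or le_mean == 0) else 0.0
    return GaapResult(
        comparison=comparison,
        depth=depth,
        observed_count=float(obs_arr.mean()),
        expected_count=float(exp_arr.mean()),
        normalized_count=float(obs_arr.mean() - exp_arr.mean()),
        sd=float((obs_arr - exp_arr).std(ddof=1)) if n_rep > 1 else 0.0,
        sh=sh_mean,
        le=le_mean,
        log2_sh_le=float(np.log2((sh_mean + ps) / (le_mean + ps))),
    )


def isoform_pair_counts(
    genes: Sequence,
    matrix,
    sample_a: str,
    sample_b: str,
    min_reads: int = 20,
) -> pd.DataFrame:
    """Build the SAAP/GAAP count table from a PaCountMatrix.

    Selects each gene's top-two 3'UTR isoforms over the comparison pair
    (>= ``min_reads`` combined) and tabulates their raw counts.
    """
    from .apa_metrics import select_top_isoforms

    rows, idx = [], []
    for gene in genes:
        pair = select_top_isoforms(gene, matrix, [sample_a, sample_b], min_reads)
        if pair is None:
            continue
        c = matrix.counts
        rows.append(
            [
                int(c.loc[pair.prox_pa.cluster_id, sample_a]),
                int(c.loc[pair.dist_pa.cluster_id, sample_a]),
                int(c.loc[pair.prox_pa.cluster_id, sample_b]),
                int(c.loc[pair.dist_pa.cluster_id, sample_b]),
            ]
        )
        idx.append(gene.gene_id)
    out = pd.DataFrame(rows, columns=COUNT_COLS, index=idx)
    return out[(out.a_prx + out.a_dis > 0) & (out.b_prx + out.b_dis > 0)]
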