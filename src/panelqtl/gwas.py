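"""Kinship, PCA covariates, panel subsetting and per-SNP mixed-model scans.

The association model per SNP is

    y = mu + covariates*gamma + x*beta + u + e,
    u ~ N(0, sg2 * K),  e ~ N(0, se2 * I)

with the variance ratio ``delta = se2/sg2`` re-estimated for every marker by
REML on the eigenbasis of the kinship matrix (one eigendecomposition per
panel; coarse log-spaced grid plus Brent refinement per marker).  The
reported effect is oriented to the panel's most common allele.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from panelqtl.simulate import GenotypeMatrix

__all__ = [
    "Kinship",
    "PanelDef",
    "AssocRecord",
    "centered_kinship",
    "genotype_pca",
    "subset_panel",
    "mlm_scan",
    "allele_stats",
    "assoc_frame",
    "DEFAULT_PANEL_PCS",
]

#: default PC-covariate counts per panel name (overridable everywhere)
DEFAULT_PANEL_PCS = {
    "All": 3, "INDAUS": 2, "JAP": 1, "IND": 1, "TEJ": 0, "TRJ": 0, "AUS": 0,
}

_DELTA_GRID = np.logspace(-5.0, 5.0, 64)


@dataclass
class Kinship:
    """Centered genotype cross-product relationship matrix."""

    matrix: np.ndarray
    accessions: list[str]
    scale: float

    def __post_init__(self) -> None:
        K = np.asarray(self.matrix, dtype=float)
        if K.shape[0] != K.shape[1] or K.shape[0] != len(self.accessions):
            raise ValueError("kinship must be square and match accession ids")
        if not np.allclose(K, K.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")
        self.matrix = K


@dataclass
class PanelDef:
    name: str
    members: list[str]
    n_pcs: int = 0

    def __post_init__(self) -> None:
        if self.n_pcs < 0:
            raise ValueError("n_pcs must be >= 0")
        if not self.members:
            raise ValueError(f"panel {self.name!r} has no members")


@dataclass
class AssocRecord:
    """Per-SNP association output row."""

    snp: str
    chrom: str
    pos: int
    minus_log10_p: float
    effect_common: float
    common_allele: str
    alt_allele: str
    n_common: int
    n_alt: int
    pct_alt: float
    trait: str = ""
    panel: str = ""

    def __post_init__(self) -> None:
        if self.minus_log10_p < 0:
            raise ValueError("minus_log10_p must be >= 0")
        if self.n_common < self.n_alt:
            raise ValueError("n_common must be >= n_alt")
        if not 0.0 <= self.pct_alt <= 100.0:
            raise ValueError("pct_alt must lie in [0, 100]")


def _impute(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing dosages per SNP; returns (filled, all_missing mask)."""
    filled = dosages.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(filled, axis=0)
    all_missing = np.isnan(means)
    means = np.where(all_missing, 0.0, means)
    nan_mask = np.isnan(filled)
    filled[nan_mask] = np.broadcast_to(means, filled.shape)[nan_mask]
    return filled, all_missing


def centered_kinship(G: GenotypeMatrix) -> Kinship:
    """K = C C' / s with C the column-centered dosages and s the summed
    per-column variance (mean column variance times SNP count), so
    trace(K) = n.  All-missing SNP columns are dropped with a warning;
    monomorphic columns contribute zero.
    """
    if G.n_accessions < 2:
        raise ValueError("kinship needs at least 2 accessions")
    filled, all_missing = _impute(G.dosages)
    if all_missing.any():
        warnings.warn(f"dropping {int(all_missing.sum())} all-missing SNP column(s)")
        filled = filled[:, ~all_missing]
    C = filled - filled.mean(axis=0, keepdims=True)
    col_var = (C * C).mean(axis=0)
    s = float(col_var.sum())
    if s <= 0:
        raise ValueError("all SNPs are monomorphic; kinship undefined")
    K = (C @ C.T) / s
    return Kinship(matrix=K, accessions=list(G.accessions), scale=s)


def genotype_pca(G: GenotypeMatrix, n_pcs: int) -> np.ndarray:
    """Scores of the top principal components of the centered dosage matrix.

    Returns an (n_accessions, n_pcs) array; ``n_pcs <= 0`` yields an empty
    covariate block.
    """
    if n_pcs >= G.n_accessions:
        raise ValueError("n_pcs must be < number of accessions")
    if n_pcs <= 0:
        return np.zeros((G.n_accessions, 0))
    filled, _ = _impute(G.dosages)
    C = filled - filled.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(C, full_matrices=False)
    return U[:, :n_pcs] * S[:n_pcs]


def subset_panel(
    G: GenotypeMatrix,
    panel: PanelDef,
    min_alt_carriers: int = 6,
) -> GenotypeMatrix:
    """Restrict to panel members, drop SNPs monomorphic within the panel, and
    flag (not drop) SNPs whose alternate allele has fewer than
    ``min_alt_carriers`` carriers; the flag lands in ``snp_map['rare']``.
    """
    index = {a: i for i, a in enumerate(G.accessions)}
    missing = [a for a in panel.members if a not in index]
    if missing:
        raise KeyError(f"panel {panel.name!r} members not in genotypes: {missing[:5]}")
    rows = [index[a] for a in panel.members]
    dos = G.dosages[rows, :]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mono = np.array([
            len(np.unique(col[~np.isnan(col)])) <= 1 for col in dos.T
        ])
    keep = ~mono
    dos = dos[:, keep]
    snp_map = G.snp_map.loc[keep].reset_index(drop=True).copy()

    n2 = (dos == 2.0).sum(axis=0)
    n0 = (dos == 0.0).sum(axis=0)
    n_alt_carriers = np.minimum(n0, n2)  # minority-allele homozygote count
    snp_map["rare"] = n_alt_carriers < min_alt_carriers

    return GenotypeMatrix(
        dos, snp_map,
        [G.accessions[i] for i in rows],
        [G.subpops[i] for i in rows],
        inbred=G.inbred,
    )


def allele_stats(
    G: GenotypeMatrix, snp: str, members: list[str] | None = None
) -> tuple[str, str, int, int, float]:
    """Carrier counts of the two homozygous classes at a SNP.

    The common allele is the one carried by more (non-missing) accessions;
    ties break to the lexicographically smaller base.  ``pct_alt`` is
    ``100 * n_alt / (n_common + n_alt)`` rounded to 2 decimals.
    """
    j = G.snp_index(snp)
    col = G.dosages[:, j]
    if members is not None:
        index = {a: i for i, a in enumerate(G.accessions)}
        col = col[[index[a] for a in members]]
    ref = str(G.snp_map.at[j, "ref"])
    alt = str(G.snp_map.at[j, "alt"])
    n_ref = int((col == 0.0).sum())
    n_altc = int((col == 2.0).sum())
    if n_ref > n_altc or (n_ref == n_altc and ref < alt):
        common, alternate, n_common, n_alt = ref, alt, n_ref, n_altc
    else:
        common, alternate, n_common, n_alt = alt, ref, n_altc, n_ref
    total = n_common + n_alt
    pct_alt = round(100.0 * n_alt / total, 2) if total else 0.0
    return common, alternate, n_common, n_alt, pct_alt


def _drop_collinear(X: np.ndarray) -> np.ndarray:
    """Drop columns beyond the numerical rank (QR pivot-free sweep)."""
    keep: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial, tol=1e-8) == len(keep) + 1:
            keep.append(j)
    if len(keep) < X.shape[1]:
        warnings.warn(f"dropping {X.shape[1] - len(keep)} collinear covariate column(s)")
    return X[:, keep]


def _batch_reml(delta, S, yt, X0t, Gt):
    """REML pieces at a per-SNP variance ratio, vectorized across SNPs.

    ``delta`` is either a scalar (shared) or an (m,) vector.  Returns
    (loglik, rss_full, rss0, beta) arrays of shape (m,).
    """
    n, m = Gt.shape
    q0 = X0t.shape[1]
    q = q0 + 1
    delta = np.broadcast_to(np.asarray(delta, dtype=float), (m,))
    W = 1.0 / (S[:, None] + delta[None, :])          # (n, m)

    # reduced-model pieces, per SNP because the weights differ
    A0 = np.einsum("ip,ij,iq->jpq", X0t, W, X0t)     # (m, q0, q0)
    b0 = np.einsum("ip,ij,i->jp", X0t, W, yt)        # (m, q0)
    yy = W.T @ (yt * yt)                             # (m,)
    A0inv = np.linalg.inv(A0)
    beta0 = np.einsum("jpq,jq->jp", A0inv, b0)
    rss0 = yy - np.einsum("jp,jp->j", b0, beta0)

    xX0 = np.einsum("ip,ij,ij->jp", X0t, W, Gt)      # (m, q0)
    xx = np.einsum("ij,ij,ij->j", Gt, W, Gt)
    xy = np.einsum("ij,ij,i->j", Gt, W, yt)
    Mv = np.einsum("jpq,jq->jp", A0inv, xX0)
    s_x = xx - np.einsum("jp,jp->j", xX0, Mv)
    r_x = xy - np.einsum("jp,jp->j", b0, Mv)

    ok = s_x > 1e-12
    s_safe = np.where(ok, s_x, 1.0)
    beta = np.where(ok, r_x / s_safe, 0.0)
    rss_full = np.where(ok, rss0 - r_x * beta, np.nan)
    rss_full = np.clip(rss_full, 1e-300, None)
    sign, logdet_A0 = np.linalg.slogdet(A0)
    logdet_w = np.log(S[:, None] + delta[None, :]).sum(axis=0)
    with np.errstate(invalid="ignore"):
        ll = -0.5 * (
            (n - q) * np.log(rss_full / (n - q))
            + logdet_w + logdet_A0 + np.log(s_safe)
            + (n - q)
        )
    ll = np.where(ok, ll, -np.inf)
    return ll, rss_full, rss0, beta


def mlm_scan(
    G: GenotypeMatrix,
    y,
    K: Kinship,
    covariates: np.ndarray | None = None,
    stat: str = "f",
    trait: str = "",
    panel: str = "",
) -> list[AssocRecord]:
    """Per-SNP mixed-linear-model scan over the eigenbasis of ``K``.

    Parameters
    ----------
    y
        Trait vector aligned to ``G.accessions`` (NaN rows are excluded).
    covariates
        Optional (n, c) fixed-covariate block (e.g. PC scores); collinear
        columns are dropped with a warning.
    stat
        ``"f"`` (default) for the marker F-test, ``"wald"`` for a 1-df
        chi-square Wald test.
    """
    if stat not in ("f", "wald"):
        raise ValueError("stat must be 'f' or 'wald'")
    y = np.asarray(pd.Series(y), dtype=float)
    if len(y) != G.n_accessions:
        raise ValueError("y must align to genotype rows")
    keep = ~np.isnan(y)
    y = y[keep]
    n = len(y)
    Kmat = K.matrix[np.ix_(keep, keep)]

    X0 = np.ones((n, 1))
    if covariates is not None and np.size(covariates) and covariates.shape[1] > 0:
        X0 = np.hstack([X0, np.asarray(covariates, dtype=float)[keep]])
        X0 = _drop_collinear(X0)
    q0 = X0.shape[1]
    q = q0 + 1

    S, U = np.linalg.eigh(Kmat)
    if S.min() < -1e-8:
        raise ValueError(f"kinship has eigenvalue {S.min():.3g} < -1e-8")
    S = np.clip(S, 0.0, None)

    filled, all_missing = _impute(G.dosages[keep, :])
    yt = U.T @ y
    X0t = U.T @ X0
    Gt = U.T @ filled

    # coarse grid sweep (shared deltas), vectorized across SNPs
    m = G.n_snps
    dos_keep = G.dosages[keep, :]
    mono = np.array([len(np.unique(c[~np.isnan(c)])) <= 1 for c in dos_keep.T])
    grid_ll = np.empty((len(_DELTA_GRID), m))
    for gi, delta in enumerate(_DELTA_GRID):
        grid_ll[gi], *_ = _batch_reml(delta, S, yt, X0t, Gt)
    best_idx = np.nanargmax(np.where(np.isfinite(grid_ll), grid_ll, -np.inf), axis=0)

    # golden-section refinement per SNP on log(delta), vectorized
    log_grid = np.log(_DELTA_GRID)
    lo = log_grid[np.maximum(best_idx - 1, 0)]
    hi = log_grid[np.minimum(best_idx + 1, len(_DELTA_GRID) - 1)]
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    c = hi - invphi * (hi - lo)
    d = lo + invphi * (hi - lo)
    fc, *_ = _batch_reml(np.exp(c), S, yt, X0t, Gt)
    fd, *_ = _batch_reml(np.exp(d), S, yt, X0t, Gt)
    for _ in range(40):  # interval shrinks by phi^-40 ~ 2e-9
        take_c = fc > fd  # keep the higher-likelihood side
        hi = np.where(take_c, d, hi)
        lo = np.where(take_c, lo, c)
        c_new = hi - invphi * (hi - lo)
        d_new = lo + invphi * (hi - lo)
        fc_new, *_ = _batch_reml(np.exp(c_new), S, yt, X0t, Gt)
        fd_new, *_ = _batch_reml(np.exp(d_new), S, yt, X0t, Gt)
        c, d, fc, fd = c_new, d_new, fc_new, fd_new
    delta_hat = np.exp(0.5 * (lo + hi))

    ll, rss_full, rss0, beta = _batch_reml(delta_hat, S, yt, X0t, Gt)
    dfe = n - q
    F = np.maximum(0.0, (rss0 - rss_full) / (rss_full / dfe))
    if stat == "f":
        p = stats.f.sf(F, 1, dfe)
    else:
        p = stats.chi2.sf(F, 1)
    p = np.clip(p, 1e-300, 1.0)
    mlp = -np.log10(p)

    # allele stats, vectorized over SNPs on the scored rows
    n_ref = (dos_keep == 0.0).sum(axis=0)
    n_altc = (dos_keep == 2.0).sum(axis=0)
    refs = G.snp_map["ref"].astype(str).to_numpy()
    alts = G.snp_map["alt"].astype(str).to_numpy()
    ref_common = (n_ref > n_altc) | ((n_ref == n_altc) & (refs < alts))

    records: list[AssocRecord] = []
    for j in range(m):
        snp = str(G.snp_map.at[j, "snp"])
        chrom = str(G.snp_map.at[j, "chrom"])
        pos = int(G.snp_map.at[j, "pos"])
        if ref_common[j]:
            common, alternate = refs[j], alts[j]
            n_common, n_alt = int(n_ref[j]), int(n_altc[j])
        else:
            common, alternate = alts[j], refs[j]
            n_common, n_alt = int(n_altc[j]), int(n_ref[j])
        total = n_common + n_alt
        pct_alt = round(100.0 * n_alt / total, 2) if total else 0.0
        if mono[j] or not np.isfinite(ll[j]):
            records.append(AssocRecord(snp, chrom, pos, 0.0, 0.0, common,
                                       alternate, n_common, n_alt, pct_alt,
                                       trait, panel))
            continue
        # beta is the per-copy effect of the alternate (alt-column) allele
        effect_common = float(beta[j]) if common == alts[j] else -float(beta[j])
        records.append(AssocRecord(snp, chrom, pos, float(mlp[j]), effect_common,
                                   common, alternate, n_common, n_alt, pct_alt,
                                   trait, panel))
    return records


def assoc_frame(records: list[AssocRecord]) -> pd.DataFrame:
    """Association records as a DataFrame mirroring the report column order."""
    cols = ["trait", "panel", "snp", "chrom", "pos", "minus_log10_p",
            "effect_common", "common_allele", "alt_allele", "n_common",
            "n_alt", "pct_alt"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)
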