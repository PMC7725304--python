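"""Synthetic data generators for the expression and electrophysiology analyses.

These generators emulate the statistical structure the analysis modules
assume — a 7-tissue x 3-replicate negative-binomial RNA-seq count design
with a planted subset of focal-tissue-specific genes, matching pairwise
differential-expression tables, and noisy activation-curve / I-V datasets
with known gating parameters — so that every pipeline can be exercised and
validated against planted ground truth without any external download.

All generators are pure functions of (parameters, seed): the same seed
gives bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gating import (
    BoltzmannParams,
    PHModelParams,
    WT_PH_PARAMS,
    open_probability,
    v_half_at_ph,
)
from .specificity import DEComparison

__all__ = [
    "TISSUES",
    "ExpressionTruth",
    "GatingTruth",
    "simulate_expression",
    "simulate_de_tables",
    "simulate_activation_curves",
    "simulate_iv_dataset",
]

#: Tissue panel of the study design: six reference organs plus the focal
#: trigger hair.
TISSUES = ("flower", "root", "petiole", "trap", "rim", "gland", "hair")


@dataclass(frozen=True)
class ExpressionTruth:
    """Design of a synthetic multi-tissue count experiment.

    ``n_planted`` genes are over-expressed ``fold``-times in the focal
    tissue; all other gene/tissue means are flat.  Baseline per-gene means
    are log-normal (so expression spans ~2 orders of magnitude); counts are
    negative binomial with variance m + dispersion*m^2.
    """

    n_genes: int = 2000
    n_planted: int = 100
    fold: float = 16.0
    tissues: tuple[str, ...] = TISSUES
    focal: str = "hair"
    n_replicates: int = 3
    dispersion: float = 0.1
    log_mean: float = 3.0
    log_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ValueError("fold must be > 1 (use fold ~ 1+eps for a null run)")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per tissue")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.focal not in self.tissues:
            raise ValueError("focal tissue must be among tissues")
        if not (0 <= self.n_planted <= self.n_genes):
            raise ValueError("0 <= n_planted <= n_genes required")


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with E = mean, Var = mean + dispersion*mean^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_expression(
    truth: ExpressionTruth,
    fold_override: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Generate replicate counts, per-tissue mean FPKM-like values, and truth.

    Returns ``(counts, means, planted)`` where ``counts`` has a
    (tissue, replicate) column MultiIndex, ``means`` is the gene x tissue
    matrix of replicate-averaged FPKM-like values, and ``planted`` is a
    boolean Series marking the planted focal-specific genes.

    ``fold_override`` replaces the enrichment fold (e.g. 1.0 for a null
    calibration run where planted genes are statistically indistinguishable).
    The FPKM-like scale uses a fixed nominal library size and a 1-kb gene
    length for all genes; specificity scoring is scale-invariant, so this
    convention is inconsequential.
    """
    rng = np.random.default_rng(truth.seed)
    fold = truth.fold if fold_override is None else fold_override
    genes = pd.Index([f"g{i:05d}" for i in range(truth.n_genes)], name="gene_id")
    planted = pd.Series(False, index=genes, name="planted")
    planted.iloc[: truth.n_planted] = True

    base = rng.lognormal(truth.log_mean, truth.log_sigma, truth.n_genes)
    cols = pd.MultiIndex.from_product(
        [truth.tissues, range(1, truth.n_replicates + 1)], names=["tissue", "replicate"]
    )
    counts = np.empty((truth.n_genes, len(cols)), dtype=np.int64)
    for j, (tissue, _rep) in enumerate(cols):
        mean = base * np.where(planted.values & (tissue == truth.focal), fold, 1.0)
        counts[:, j] = _nb_counts(rng, mean, truth.dispersion)
    counts = pd.DataFrame(counts, index=genes, columns=cols)

    # FPKM-like: counts * 1e9 / (length_bp * library_size) with the fixed
    # nominal convention length = 1 kb, library = 1e6 -> numerically the count.
    fpkm = counts.astype(float)
    means = fpkm.T.groupby(level="tissue").mean().T[list(truth.tissues)]
    return counts, means, planted


def _moderated_two_sample_test(
    log_a: np.ndarray, log_b: np.ndarray, prior_df: float = 20.0
) -> np.ndarray:
    """Two-sample test on log counts with variance moderation across genes.

    Per-gene pooled variances are shrunk toward their across-gene mean with
    ``prior_df`` pseudo-degrees of freedom (a fixed-prior moderated t in the
    spirit of limma-trend); the reference distribution is t with
    n1 + n2 - 2 + prior_df degrees of freedom.  Returns two-sided p-values.
    """
    n1, n2 = log_a.shape[1], log_b.shape[1]
    m1, m2 = log_a.mean(axis=1), log_b.mean(axis=1)
    s2 = (
        log_a.var(axis=1, ddof=1) * (n1 - 1) + log_b.var(axis=1, ddof=1) * (n2 - 1)
    ) / (n1 + n2 - 2)
    s2_prior = s2.mean()
    df_res = n1 + n2 - 2
    s2_mod = (prior_df * s2_prior + df_res * s2) / (prior_df + df_res)
    se = np.sqrt(s2_mod * (1.0 / n1 + 1.0 / n2))
    t = (m1 - m2) / se
    return 2.0 * stats.t.sf(np.abs(t), df=df_res + prior_df)


def simulate_de_tables(
    counts: pd.DataFrame,
    focal: str = "hair",
    pseudocount: float = 1.0,
    prior_df: float = 20.0,
) -> list[DEComparison]:
    """Stand-in differential-expression step for the intersection analysis.

    For every non-focal tissue the focal replicates are compared with a
    moderated two-sample test on log(count + pseudocount); p-values are
    BH-adjusted across genes within each comparison.  log2FC is the log2
    ratio of group means (with pseudocount) and ``focal_counts`` the focal
    replicate mean.  This is deliberately simple test plumbing, not a
    reimplementation of a published RNA-seq DE method.
    """
    tissues = counts.columns.get_level_values("tissue").unique()
    if focal not in tissues:
        raise ValueError(f"focal tissue {focal!r} not in count columns")
    focal_block = counts[focal].to_numpy(dtype=float)
    if focal_block.shape[1] < 2:
        raise ValueError("need >= 2 replicates per tissue")
    log_focal = np.log(focal_block + pseudocount)
    focal_mean = focal_block.mean(axis=1)

    tables: list[DEComparison] = []
    for other in tissues:
        if other == focal:
            continue
        block = counts[other].to_numpy(dtype=float)
        if block.shape[1] < 2:
            raise ValueError("need >= 2 replicates per tissue")
        log_other = np.log(block + pseudocount)
        p = _moderated_two_sample_test(log_focal, log_other, prior_df=prior_df)
        padj = multipletests(p, method="fdr_bh")[1]
        log2fc = np.log2(
            (focal_mean + pseudocount) / (block.mean(axis=1) + pseudocount)
        )
        tables.append(
            DEComparison(
                focal=focal,
                other=str(other),
                table=pd.DataFrame(
                    {
                        "gene_id": counts.index,
                        "log2fc": log2fc,
                        "padj": padj,
                        "focal_counts": focal_mean,
                    }
                ),
            )
        )
    return tables


@dataclass(frozen=True)
class GatingTruth:
    """Design of a synthetic activation-curve experiment."""

    params: BoltzmannParams = field(
        default_factory=lambda: BoltzmannParams(a=0.6, v_half=-120.0)
    )
    sigma: float = 0.03
    voltages: tuple[float, ...] = tuple(np.linspace(-200.0, -50.0, 16))
    n_cells: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if len(self.voltages) < 5:
            raise ValueError("need >= 5 test voltages")


def simulate_activation_curves(truth: GatingTruth) -> pd.DataFrame:
    """Relative open probabilities po(V) + Gaussian noise, per cell.

    Returns a long DataFrame with columns ``cell_id``, ``V_mV``, ``rel_po``.
    Noise values above 1 are retained; at sigma = 0 the generating
    parameters are exactly recoverable by a Boltzmann fit.
    """
    rng = np.random.default_rng(truth.seed)
    v = np.asarray(truth.voltages, dtype=float)
    frames = []
    for cell in range(1, truth.n_cells + 1):
        po = open_probability(v, truth.params) + rng.normal(0.0, truth.sigma, v.size)
        frames.append(pd.DataFrame({"cell_id": cell, "V_mV": v, "rel_po": po}))
    return pd.concat(frames, ignore_index=True)


def simulate_iv_dataset(
    conditions: list[dict],
    ph_params: PHModelParams = WT_PH_PARAMS,
    voltages: tuple[float, ...] = tuple(np.arange(40.0, -201.0, -10.0)),
    k_internal: float = 100.0,
    conductance: float = 0.1,
    n_cells: int = 4,
    sigma: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic two-electrode voltage-clamp I-V dataset.

    Each condition is a dict with keys ``k_ext`` (mM), ``ph``, and optional
    ``blocker`` (label) and ``block_factor`` (residual conductance fraction,
    e.g. 0.1 for a 90% block).  Currents follow the open-channel model

        I(V) = G * g_cell * block * po(V; V1/2(pH)) * (V - E_K)

    with V1/2 from the pH model, E_K the Nernst potential of the K+
    gradient, a per-cell amplitude factor ``g_cell`` (lognormal, mimicking
    the large cell-to-cell variance of oocyte expression), and optional
    Gaussian noise.  Returns columns ``cell_id``, ``condition``, ``K_ext``,
    ``pH``, ``blocker``, ``V_mV``, ``I``.
    """
    rng = np.random.default_rng(seed)
    v = np.asarray(voltages, dtype=float)
    g_cell = rng.lognormal(0.0, 0.3, n_cells)
    rows = []
    for cond in conditions:
        k_ext = float(cond["k_ext"])
        ph = float(cond["ph"])
        blocker = str(cond.get("blocker", "none"))
        block = float(cond.get("block_factor", 1.0))
        label = cond.get("label", f"K{k_ext:g}_pH{ph:g}_{blocker}")
        v_half = v_half_at_ph(ph, ph_params)
        bp = BoltzmannParams(ph_params.a, v_half, ph_params.rt_over_f)
        e_k = ph_params.rt_over_f * np.log(k_ext / k_internal)
        po = open_probability(v, bp)
        for cell in range(1, n_cells + 1):
            current = conductance * g_cell[cell - 1] * block * po * (v - e_k)
            if sigma > 0:
                current = current + rng.normal(0.0, sigma, v.size)
            rows.append(
                pd.DataFrame(
                    {
                        "cell_id": cell,
                        "condition": label,
                        "K_ext": k_ext,
                        "pH": ph,
                        "blocker": blocker,
                        "V_mV": v,
                        "I": current,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
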