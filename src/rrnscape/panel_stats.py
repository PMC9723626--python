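"""Panel-level statistics.

* sliding-window gene persistence along a chromosome (81-CDS window, 1-CDS
  step, truncated at the ends);
* median-of-ratios size factors and per-kb log2 normalization of expression
  counts;
* compartment-stratified Spearman correlations of expression against
  persistence and against distance to the replication origin, over the four
  strata CCC / CCNC / TCC / TCNC (central vs terminal x core vs non-core);
* Fisher exact enrichment (odds ratio ad/bc with the exact two-sided p);
* forward/backward stepwise OLS selection by AIC for the core-region-size
  model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .compartments import CompartmentMap
from .genome_model import GenomeAnnotation


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def windowed_persistence(values: Sequence[float], window: int = 81) -> np.ndarray:
    """Centered sliding-window mean, truncated at the chromosome ends.

    Output has the same length as the input (one value per CDS, 1-CDS step).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) == 0:
        raise ValueError("values must be a non-empty 1-D sequence")
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(v)])
    n = len(v)
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def persistence_track(
    genome: GenomeAnnotation, persistence: Mapping[str, float], window: int = 81
) -> pd.DataFrame:
    """Windowed persistence along one genome's CDSs (chromosomal order)."""
    cds = [g for g in genome.genes if g.kind == "CDS"]
    raw = [persistence.get(g.orthogroup_id, 0.0) for g in cds]
    return pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in cds],
            "position": [g.midpoint for g in cds],
            "persistence": raw,
            "windowed": windowed_persistence(raw, window),
        }
    )


# ---------------------------------------------------------------------------
# Expression normalization
# ---------------------------------------------------------------------------


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (one per sample/column).

    The reference is the gene-wise geometric mean across samples; genes with
    a zero count in any sample are excluded from the reference.
    """
    mat = counts.to_numpy(dtype=float)
    keep = (mat > 0).all(axis=1)
    if not keep.any():
        raise ValueError("no gene has positive counts in all samples")
    logref = np.log(mat[keep]).mean(axis=1)
    factors = np.exp(np.median(np.log(mat[keep]) - logref[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_per_kb(
    counts: pd.DataFrame,
    lengths_bp: Mapping[str, float],
    factors: Optional[pd.Series] = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """log2 of size-factor-normalized counts per kb of gene length."""
    if factors is None:
        factors = size_factors(counts)
    lk = pd.Series({g: lengths_bp[g] / 1000.0 for g in counts.index})
    normed = counts.div(factors, axis=1).div(lk, axis=0)
    return np.log2(normed + pseudocount)


# ---------------------------------------------------------------------------
# Stratified correlations
# ---------------------------------------------------------------------------

STRATA = ("CCC", "CCNC", "TCC", "TCNC")


def stratify_genes(
    genome: GenomeAnnotation, cmap: CompartmentMap, core_group_ids
) -> pd.Series:
    """Stratum per CDS: central/terminal x core/non-core."""
    core = set(core_group_ids)
    out = {}
    for g in genome.genes:
        if g.kind != "CDS":
            continue
        central = cmap.in_central(g.midpoint)
        is_core = g.orthogroup_id in core
        out[g.gene_id] = ("C" if central else "T") + ("CC" if is_core else "CNC")
    return pd.Series(out, name="stratum")


def compartment_correlations(
    genome: GenomeAnnotation,
    expression: Mapping[str, float],
    persistence: Mapping[str, float],
    cmap: CompartmentMap,
    core_group_ids,
) -> pd.DataFrame:
    """Spearman rho of expression vs persistence and vs |distance to oriC|,
    per stratum and pooled."""
    strata = stratify_genes(genome, cmap, core_group_ids)
    oric = genome.oric_position
    rows = []
    cds = [g for g in genome.genes if g.kind == "CDS" and g.gene_id in expression]
    frame = pd.DataFrame(
        {
            "expr": [expression[g.gene_id] for g in cds],
            "pers": [persistence.get(g.orthogroup_id, 0.0) for g in cds],
            "dist": [abs(g.midpoint - oric) for g in cds],
            "stratum": [strata[g.gene_id] for g in cds],
        }
    )
    for name, sub in [("pooled", frame)] + [
        (s, frame[frame.stratum == s]) for s in STRATA
    ]:
        if len(sub) < 3:
            rows.append((name, len(sub), np.nan, np.nan, np.nan, np.nan))
            continue

        def _rho(x, y):
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                return type("R", (), {"statistic": np.nan, "pvalue": np.nan})
            return stats.spearmanr(x, y)

        rp = _rho(sub.expr.to_numpy(), sub.pers.to_numpy())
        rd = _rho(sub.expr.to_numpy(), sub.dist.to_numpy())
        rows.append(
            (name, len(sub), rp.statistic, rp.pvalue, rd.statistic, rd.pvalue)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "stratum",
            "n",
            "rho_persistence",
            "p_persistence",
            "rho_distance",
            "p_distance",
        ],
    ).set_index("stratum")


def median_expression_by_compartment(
    genome: GenomeAnnotation, expression: Mapping[str, float], cmap: CompartmentMap
) -> dict:
    central, terminal = [], []
    for g in genome.genes:
        if g.kind != "CDS" or g.gene_id not in expression:
            continue
        (central if cmap.in_central(g.midpoint) else terminal).append(
            expression[g.gene_id]
        )
    return {
        "central": float(np.median(central)) if central else np.nan,
        "terminal": float(np.median(terminal)) if terminal else np.nan,
    }


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------


def fisher_enrichment(a: int, b: int, c: int, d: int):
    """Sample odds ratio ad/bc and the exact two-sided p for [[a, b], [c, d]]."""
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


# ---------------------------------------------------------------------------
# Stepwise AIC model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelFit:
    selected: tuple
    coefficients: dict
    aic: float
    selected_forward: tuple
    aic_forward: float
    selected_backward: tuple
    aic_backward: float
    r_pred_obs: float
    n: int


def _design(frame: pd.DataFrame, candidates) -> dict:
    """Candidate -> design block (categoricals become dummy blocks)."""
    blocks = {}
    for c in candidates:
        col = frame[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=c, drop_first=True).astype(float)
            blocks[c] = dummies.to_numpy()
        else:
            blocks[c] = col.to_numpy(dtype=float)[:, None]
    return blocks


def _fit(y, X):
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    return beta, rss, rank


def _aic(y, blocks, subset):
    n = len(y)
    X = np.hstack([np.ones((n, 1))] + [blocks[c] for c in subset]) if subset else np.ones((n, 1))
    beta, rss, rank = _fit(y, X)
    if rank < X.shape[1]:
        return None, None  # collinear design
    p = X.shape[1]
    return n * np.log(max(rss, 1e-300) / n) + 2 * (p + 1), beta


def stepwise_model(
    features: pd.DataFrame,
    response: str = "core_region_size",
    candidates: Optional[Iterable[str]] = None,
    direction: str = "both",
) -> ModelFit:
    """Forward and backward stepwise OLS selection minimizing AIC.

    AIC = n ln(RSS/n) + 2(p+1) up to an additive constant, which cancels in
    comparisons.  Exactly collinear candidates are dropped with a warning;
    both passes are reported and the lower-AIC result wins.
    """
    y = features[response].to_numpy(dtype=float)
    n = len(y)
    if candidates is None:
        candidates = [c for c in features.columns if c != response]
    candidates = list(candidates)
    blocks = _design(features, candidates)
    width = sum(b.shape[1] for b in blocks.values())
    if n <= width + 1:
        raise ValueError(f"n={n} too small for {width} candidate columns")
    # drop exactly collinear candidates up front
    usable = []
    for c in candidates:
        aic_val, _ = _aic(y, blocks, usable + [c])
        if aic_val is None:
            warnings.warn(f"candidate {c!r} is collinear with others; dropped",
                          stacklevel=2)
        else:
            usable.append(c)
    candidates = usable

    def forward():
        selected: list = []
        current, _ = _aic(y, blocks, selected)
        while True:
            best = None
            for c in candidates:
                if c in selected:
                    continue
                a, _ = _aic(y, blocks, selected + [c])
                if a is not None and (best is None or a < best[0]):
                    best = (a, c)
            if best is None or best[0] >= current:
                return tuple(selected), current
            current = best[0]
            selected.append(best[1])

    def backward():
        selected = list(candidates)
        current, _ = _aic(y, blocks, selected)
        while selected:
            best = None
            for c in selected:
                a, _ = _aic(y, blocks, [s for s in selected if s != c])
                if a is not None and (best is None or a < best[0]):
                    best = (a, c)
            if best is None or best[0] >= current:
                break
            current = best[0]
            selected.remove(best[1])
        return tuple(selected), current

    sel_f, aic_f = forward()
    sel_b, aic_b = backward()
    if direction == "forward":
        sel, aic_val = sel_f, aic_f
    elif direction == "backward":
        sel, aic_val = sel_b, aic_b
    else:
        sel, aic_val = (sel_f, aic_f) if aic_f <= aic_b else (sel_b, aic_b)
    X = np.hstack(
        [np.ones((n, 1))] + [blocks[c] for c in sel]
    ) if sel else np.ones((n, 1))
    beta, _, _ = _fit(y, X)
    pred = X @ beta
    r = float(np.corrcoef(pred, y)[0, 1]) if len(sel) else 0.0
    names = ["intercept"]
    for c in sel:
        w = blocks[c].shape[1]
        names.extend([c] if w == 1 else [f"{c}[{j}]" for j in range(w)])
    return ModelFit(
        selected=tuple(sel),
        coefficients=dict(zip(names, beta.tolist())),
        aic=float(aic_val),
        selected_forward=sel_f,
        aic_forward=float(aic_f),
        selected_backward=sel_b,
        aic_backward=float(aic_b),
        r_pred_obs=r,
        n=n,
    )
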