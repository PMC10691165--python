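"""Per-sample immune scoring and cohort stratification.

The immune score summarises how well a sample's T cells keep proliferating in
the face of immunosuppressive signalling (TGF-b1 / TRAIL / PGE2 type
signals).  Per T cell we compute a suppression activity ``c`` (mean
normalised expression over the suppression signature) and a proliferation
signal ``p`` (mean over proliferation up-genes minus down-genes), regress
``p = b0 + b1 * c`` across the sample's T cells, and report the score
``-b1 / SE(b1)``.  This is a documented, self-contained resilience
regression; externally computed scores (e.g. from a full T-cell resilience
model run) can be injected into :func:`stratify` unchanged.

Cohort stratification uses a score of 0 as the responsive/non-responsive
cutoff and labels the top 10% of samples (by score, among scores > 0) as the
high tier; remaining positive samples are the middle tier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import (DEFAULT_T_CELL_LABELS, ExpressionMatrix,
                         ValidationError, normalize_log2_tpm)

TIERS = ("high", "middle", "low")


@dataclass
class SignatureSet:
    """A named gene signature with up- and down-regulated members."""

    name: str
    up_genes: list[str]
    down_genes: list[str]

    def __post_init__(self) -> None:
        self.up_genes = [str(g).upper() for g in self.up_genes]
        self.down_genes = [str(g).upper() for g in self.down_genes]
        if not self.up_genes and not self.down_genes:
            raise ValidationError(f"signature {self.name!r} is empty")


def read_signature_set(path: str | Path, name: str | None = None) -> SignatureSet:
    """Read a two-column TSV (gene, direction in {up, down})."""
    tab = pd.read_csv(path, sep="\t", header=None, names=["gene", "direction"])
    bad = set(tab["direction"]) - {"up", "down"}
    if bad:
        raise ValidationError(f"unknown signature directions: {sorted(bad)}")
    return SignatureSet(
        name=name or Path(path).stem,
        up_genes=tab.loc[tab["direction"] == "up", "gene"].tolist(),
        down_genes=tab.loc[tab["direction"] == "down", "gene"].tolist(),
    )


def pseudobulk_tcells(m: ExpressionMatrix,
                      meta: pd.DataFrame,
                      t_cell_labels: set[str] | None = None) -> pd.DataFrame:
    """Aggregate T-cell counts per sample into normalised pseudo-bulk rows.

    Counts of all T cells in a sample are summed gene-wise, normalised as
    log2(TPM/10 + 1), and each gene is then centred to zero mean across the
    input samples, so a profile is only meaningful relative to its cohort.
    """
    t_cell_labels = t_cell_labels or DEFAULT_T_CELL_LABELS
    meta = meta[meta["cell_id"].isin(set(m.cell_ids))].set_index("cell_id")
    rows, ids = [], []
    for sample_id, grp in meta.groupby("sample_id", sort=True):
        t_cells = grp.index[grp["cell_type"].isin(t_cell_labels)]
        if len(t_cells) == 0:
            warnings.warn(f"sample {sample_id!r} has no T cells; skipped")
            continue
        mask = np.isin(m.cell_ids, np.asarray(t_cells, dtype=object))
        agg = np.asarray(m.counts[mask].sum(axis=0)).ravel()
        rows.append(agg)
        ids.append(str(sample_id))
    if not rows:
        raise ValidationError("no sample contains any T cells")
    bulk = ExpressionMatrix(
        cell_ids=np.asarray(ids, dtype=object),
        gene_ids=m.gene_ids.copy(),
        counts=np.vstack(rows),
    )
    bulk = normalize_log2_tpm(bulk)
    prof = pd.DataFrame(bulk.norm, index=ids, columns=m.gene_ids)
    if len(ids) == 1:
        warnings.warn("single-sample pseudo-bulk: zero-mean scaling yields an "
                      "all-zero profile; cohort context is required")
    return prof - prof.mean(axis=0)


def _signature_activity(norm: pd.DataFrame, sig: SignatureSet) -> np.ndarray:
    """Per-cell mean over up-genes minus mean over down-genes."""
    up = [g for g in sig.up_genes if g in norm.columns]
    down = [g for g in sig.down_genes if g in norm.columns]
    if not up and not down:
        raise ValidationError(
            f"no gene of signature {sig.name!r} is present in the matrix"
        )
    act = np.zeros(len(norm))
    if up:
        act += norm[up].to_numpy().mean(axis=1)
    if down:
        act -= norm[down].to_numpy().mean(axis=1)
    return act


def resilience_score(tcell_norm: pd.DataFrame,
                     suppression: SignatureSet,
                     proliferation: SignatureSet,
                     min_cells: int = 10) -> float:
    """Score one sample's T cells: -slope/SE of p ~ c.

    ``tcell_norm`` is the cells x genes normalised matrix of the sample's T
    cells.  A positive score means proliferation falls steeply as the
    suppressive signal rises (large negative slope), per this stand-in's
    sign convention; degenerate suppression variance yields 0.
    """
    from scipy import stats

    if len(tcell_norm) < min_cells:
        raise ValidationError(
            f"need at least {min_cells} T cells, got {len(tcell_norm)}"
        )
    c = _signature_activity(tcell_norm, suppression)
    p = _signature_activity(tcell_norm, proliferation)
    if np.ptp(c) == 0 or not np.isfinite(c).all():
        warnings.warn("suppression activity is constant across T cells; "
                      "score set to 0")
        return 0.0
    fit = stats.linregress(c, p)
    if not np.isfinite(fit.stderr) or fit.stderr == 0:
        warnings.warn("degenerate regression; score set to 0")
        return 0.0
    return float(-fit.slope / fit.stderr)


def score_samples(m: ExpressionMatrix,
                  meta: pd.DataFrame,
                  suppression: SignatureSet,
                  proliferation: SignatureSet,
                  t_cell_labels: set[str] | None = None,
                  min_cells: int = 10) -> pd.DataFrame:
    """Resilience score per sample; samples with too few T cells are skipped."""
    t_cell_labels = t_cell_labels or DEFAULT_T_CELL_LABELS
    if m.norm is None:
        m = normalize_log2_tpm(m)
    norm = m.norm_frame()
    idx = meta[meta["cell_id"].isin(set(m.cell_ids))].set_index("cell_id")
    out = []
    for sample_id, grp in idx.groupby("sample_id", sort=True):
        t_cells = grp.index[grp["cell_type"].isin(t_cell_labels)]
        if len(t_cells) < min_cells:
            warnings.warn(f"sample {sample_id!r} has {len(t_cells)} T cells "
                          f"(< {min_cells}); not scored")
            continue
        score = resilience_score(norm.loc[list(t_cells)], suppression,
                                 proliferation, min_cells=min_cells)
        out.append({"sample_id": str(sample_id), "score": score,
                    "n_t_cells": len(t_cells)})
    return pd.DataFrame(out, columns=["sample_id", "score", "n_t_cells"])


def stratify(scores: pd.DataFrame) -> pd.DataFrame:
    """Assign high/middle/low tiers from per-sample scores.

    Samples with score <= 0 are low.  Among positive scores, the top
    floor(0.10 * n_cohort) by score are high (cohorts smaller than 10 get no
    high tier); the remaining positive samples are middle.  Ties at the high
    boundary are broken by sample_id order, deterministically.
    """
    if "sample_id" not in scores.columns or "score" not in scores.columns:
        raise ValidationError("scores must have sample_id and score columns")
    out = scores.copy().reset_index(drop=True)
    if out.empty:
        out["tier"] = pd.Series(dtype=object)
        return out
    if out["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in scores")
    n = len(out)
    n_high = int(np.floor(0.10 * n))
    tier = np.where(out["score"] <= 0, "low", "middle").astype(object)
    positive = out.index[out["score"] > 0]
    if n_high > 0 and len(positive) > 0:
        order = out.loc[positive].sort_values(
            ["score", "sample_id"], ascending=[False, True]
        ).index[: min(n_high, len(positive))]
        tier[np.asarray(order)] = "high"
    out["tier"] = tier
    return out
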