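"""End-to-end orchestration: QC -> immune tiering -> tier-specific therapy.

High-tier samples are recommended for checkpoint-inhibitor immunotherapy
alone.  Low-tier samples go down the malignant-cluster route: drug-response
driven clustering, sensitivity transfer from the reference panel and
bipartite combination optimization.  Middle-tier samples go down the
exhaustion-trajectory route: trajectory scoring, differential signatures and
perturbation-reversal drug scoring feed the same optimizer with trajectories
as the cell groups (t_j = end-type cell count).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import combination, immune, trajectories
from .clustering import ClusteringProblem, ClusteringResult, optimize_resolution
from .config import Config
from .expression import (DEFAULT_T_CELL_LABELS, ExpressionMatrix,
                         check_sample_inclusion, normalize_log2_tpm, qc_filter)
from .trajectories import DEFAULT_TRAJECTORIES, SignatureLibrary
from .transfer import ReferencePanel


@dataclass
class SampleResult:
    sample_id: str
    tier: str
    strategy: str
    clustering: ClusteringResult | None = None
    trajectory_results: list = field(default_factory=list)
    solution: combination.CombinationSolution | None = None
    notes: list[str] = field(default_factory=list)


@dataclass
class PipelineResult:
    scores: pd.DataFrame
    inclusion: list
    samples: dict[str, SampleResult] = field(default_factory=dict)


def run_pipeline(m: ExpressionMatrix,
                 meta: pd.DataFrame,
                 panel: ReferencePanel,
                 library: SignatureLibrary | None = None,
                 side_effects: pd.DataFrame | None = None,
                 suppression: immune.SignatureSet | None = None,
                 proliferation: immune.SignatureSet | None = None,
                 scores: pd.DataFrame | None = None,
                 velocity: dict | None = None,
                 cfg: Config | None = None,
                 t_cell_labels: set[str] | None = None,
                 trajectory_defs=DEFAULT_TRAJECTORIES) -> PipelineResult:
    """Run QC, stratification and the tier-appropriate optimization per sample.

    ``scores`` may carry externally computed immune scores (sample_id,
    score); otherwise the built-in resilience regression is used, which
    requires the suppression and proliferation signature sets.
    """
    cfg = cfg or Config()
    t_cell_labels = t_cell_labels or DEFAULT_T_CELL_LABELS
    m, _ = qc_filter(m, cfg)
    meta = meta[meta["cell_id"].isin(set(m.cell_ids))].reset_index(drop=True)
    m = normalize_log2_tpm(m)
    inclusion = check_sample_inclusion(meta, cfg, t_cell_labels)
    if scores is None:
        if suppression is None or proliferation is None:
            raise ValueError("either external scores or both signature sets "
                             "are required")
        scores = immune.score_samples(m, meta, suppression, proliferation,
                                      t_cell_labels)
    tiers = immune.stratify(scores)
    result = PipelineResult(scores=tiers, inclusion=inclusion)
    norm = m.norm_frame()
    for _, row in tiers.iterrows():
        sample_id, tier = str(row["sample_id"]), str(row["tier"])
        smeta = meta[meta["sample_id"] == sample_id]
        sres = SampleResult(sample_id=sample_id, tier=tier, strategy="")
        if tier == "high":
            sres.strategy = "immune checkpoint inhibitor monotherapy"
        elif tier == "low":
            sres.strategy = "malignant-cluster drug combination"
            _run_low(sres, norm, smeta, panel, side_effects, velocity, cfg)
        else:
            sres.strategy = "trajectory-reversal drugs paired with ICB"
            _run_middle(sres, m, smeta, library, side_effects, cfg,
                        trajectory_defs)
        result.samples[sample_id] = sres
    return result


def _run_low(sres: SampleResult, norm: pd.DataFrame, smeta: pd.DataFrame,
             panel: ReferencePanel, side_effects, velocity, cfg: Config) -> None:
    mal_cells = smeta.loc[smeta["is_malignant"], "cell_id"]
    if len(mal_cells) < 2:
        sres.notes.append("too few malignant cells; skipped")
        return
    problem = ClusteringProblem(
        cells_norm=norm.loc[list(mal_cells)], panel=panel,
        alpha=cfg.alpha_sim, eps=cfg.eps_divergence,
    )
    clu = optimize_resolution(problem, seed=cfg.seed, cfg=cfg)
    sres.clustering = clu
    V = None
    if velocity:
        V = np.array([float(velocity.get(c, 0.0)) for c in clu.W.columns])
    bp = combination.from_response_matrix(
        clu.W, t=clu.cell_numbers, V=V, side_effects=side_effects,
        lam=cfg.lambda_side_effect, respond_threshold=cfg.respond_threshold,
    )
    sres.solution = combination.solve(bp)


def _run_middle(sres: SampleResult, m: ExpressionMatrix, smeta: pd.DataFrame,
                library: SignatureLibrary | None, side_effects, cfg: Config,
                trajectory_defs) -> None:
    if library is None:
        sres.notes.append("no signature library provided; skipped")
        return
    sub = m.subset_cells(smeta["cell_id"].to_numpy(dtype=object))
    results = trajectories.analyze_trajectories(
        sub, smeta, trajectory_defs, min_cells=cfg.min_trajectory_cells
    )
    sres.trajectory_results = results
    live = [r for r in results if r.exists]
    if not live:
        sres.notes.append("no trajectory exists in this sample")
        return
    W = trajectories.trajectory_drug_matrix(results, library)
    t = np.array([r.n_end for r in live], dtype=float)
    bp = combination.from_response_matrix(
        W, t=t, side_effects=side_effects, lam=cfg.lambda_side_effect,
        respond_threshold=cfg.respond_threshold,
    )
    sres.solution = combination.solve(bp)
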