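"""Synthetic fixture generation for the full pipeline.

The generator emulates the shapes of every external input the workflow
consumes — a UMI count matrix with cell metadata, a cell-line reference
panel with drug sensitivities, a signed drug perturbation signature library
and a side-effect frequency table — with planted structure whose recovery
the tests check end to end:

* one sample carries two well-separated malignant clusters, each matched by
  a dedicated reference line that is sensitive to exactly one drug, so the
  optimal combination is the planted drug pair;
* T cells per sample carry a planted proliferation-vs-suppression relation
  whose sign determines the sample's immune tier;
* one middle-tier sample contains exhaustion-trajectory endpoints with a
  planted differential block, and the library holds a drug whose signature
  exactly negates it;
* two drugs are planted at the toxicity boundary (12 vs 10 side effects at
  40% frequency).

Counts are negative binomial (dispersion 0.5) with Bernoulli dropout; all
randomness flows from the spec seed through named substreams, so equal
seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, ValidationError
from .immune import SignatureSet
from .trajectories import DEFAULT_TRAJECTORIES, SignatureLibrary
from .transfer import ReferencePanel

_STREAMS = {"means": 1, "counts": 2, "panel": 3, "signatures": 4, "tfactors": 5}


@dataclass
class FixtureSpec:
    n_genes: int = 300
    n_clusters: int = 2                 # planted malignant clusters
    cells_per_cluster: int = 150
    n_samples: int = 4
    t_cells_per_sample: int = 80
    mito_fraction_range: tuple[float, float] = (0.005, 0.03)
    dropout_rate: float = 0.1
    dispersion: float = 0.5
    n_lines: int = 4
    n_drugs: int = 6
    planted_sensitivity: dict[int, str] | None = None  # cluster -> drug
    cluster_means: np.ndarray | None = None            # clusters x genes
    marker_fold: float = 10.0
    deg_fold: float = 10.0
    panel_noise_sd: float = 0.05
    seed: int = 0

    # gene-block bookkeeping
    n_mito: int = 10
    n_signature_genes: int = 8
    n_deg_genes: int = 10
    n_marker_genes: int = 30

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_clusters, self.cells_per_cluster,
               self.n_samples, self.t_cells_per_sample, self.n_lines,
               self.n_drugs) < 1:
            raise ValidationError("all fixture sizes must be positive")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValidationError("dropout_rate must lie in [0, 1]")
        lo, hi = self.mito_fraction_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValidationError("mito_fraction_range must lie in [0, 1]")
        if self.planted_sensitivity is None:
            self.planted_sensitivity = {
                c: _drug_name(c) for c in range(self.n_clusters)
            }
        n_special = (self.n_mito + 2 * self.n_signature_genes
                     + len(DEFAULT_TRAJECTORIES) * self.n_deg_genes
                     + self.n_clusters * self.n_marker_genes)
        if self.n_genes <= n_special:
            raise ValidationError(
                f"n_genes must exceed {n_special} to fit the planted blocks"
            )

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


def _drug_name(i: int) -> str:
    return f"DRUG_{chr(ord('A') + i)}"


def gene_layout(spec: FixtureSpec) -> dict:
    """Named gene blocks; every id is an uppercase symbol."""
    blocks: dict = {}
    blocks["mito"] = [f"MT-G{i + 1}" for i in range(spec.n_mito)]
    blocks["suppression"] = [f"SUPG{i + 1}"
                             for i in range(spec.n_signature_genes)]
    blocks["proliferation"] = [f"PROG{i + 1}"
                               for i in range(spec.n_signature_genes)]
    blocks["trajectory"] = {
        td.name: [f"TRJ{t + 1}G{i + 1}" for i in range(spec.n_deg_genes)]
        for t, td in enumerate(DEFAULT_TRAJECTORIES)
    }
    blocks["markers"] = {
        c: [f"MK{c + 1}G{i + 1}" for i in range(spec.n_marker_genes)]
        for c in range(spec.n_clusters)
    }
    used = (len(blocks["mito"]) + len(blocks["suppression"])
            + len(blocks["proliferation"])
            + sum(len(v) for v in blocks["trajectory"].values())
            + sum(len(v) for v in blocks["markers"].values()))
    blocks["background"] = [f"BGG{i + 1}"
                            for i in range(spec.n_genes - used)]
    genes = (blocks["mito"] + blocks["suppression"] + blocks["proliferation"]
             + [g for v in blocks["trajectory"].values() for g in v]
             + [g for v in blocks["markers"].values() for g in v]
             + blocks["background"])
    blocks["genes"] = genes
    return blocks


def immune_signatures(spec: FixtureSpec) -> tuple[SignatureSet, SignatureSet]:
    """Suppression and proliferation gene sets matching the layout."""
    blocks = gene_layout(spec)
    return (
        SignatureSet("suppression", up_genes=blocks["suppression"],
                     down_genes=[]),
        SignatureSet("proliferation", up_genes=blocks["proliferation"],
                     down_genes=[]),
    )


def _baseline_means(spec: FixtureSpec) -> pd.Series:
    blocks = gene_layout(spec)
    rng = spec.rng("means")
    base = pd.Series(rng.gamma(2.0, 1.5, size=spec.n_genes),
                     index=blocks["genes"])
    base[blocks["suppression"]] = 20.0
    base[blocks["proliferation"]] = 20.0
    for genes in blocks["trajectory"].values():
        base[genes] = 5.0
    lo, hi = spec.mito_fraction_range
    target_frac = (lo + hi) / 2.0
    non_mito = float(base.drop(blocks["mito"]).sum())
    base[blocks["mito"]] = (
        target_frac * non_mito / ((1.0 - target_frac) * spec.n_mito)
    )
    return base


def cluster_mean_matrix(spec: FixtureSpec) -> pd.DataFrame:
    """Per-malignant-cluster gene means (markers boosted, others damped)."""
    if spec.cluster_means is not None:
        blocks = gene_layout(spec)
        return pd.DataFrame(np.asarray(spec.cluster_means, dtype=float),
                            columns=blocks["genes"])
    blocks = gene_layout(spec)
    base = _baseline_means(spec)
    rows = []
    for c in range(spec.n_clusters):
        mu = base.copy()
        mu[blocks["markers"][c]] *= spec.marker_fold
        for other in range(spec.n_clusters):
            if other != c:
                mu[blocks["markers"][other]] *= 0.1
        rows.append(mu)
    return pd.DataFrame(rows, index=range(spec.n_clusters))


def _sample_counts(rng: np.random.Generator, mu: np.ndarray,
                   dispersion: float, dropout: float) -> np.ndarray:
    mu = np.clip(np.asarray(mu, dtype=float), 0.0, None)
    r = 1.0 / dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    if dropout > 0:
        counts = counts * (rng.random(counts.shape) >= dropout)
    return counts


def planted_tiers(spec: FixtureSpec) -> dict[str, str]:
    """Sample S1 is the planted low-tier sample; the rest are middle."""
    tiers = {}
    for s in range(spec.n_samples):
        tiers[f"S{s + 1}"] = "low" if s == 0 else "middle"
    return tiers


def simulate_scrna(spec: FixtureSpec) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Counts + metadata with planted clusters, tiers and trajectories.

    Malignant clusters live in sample S1 (the planted low-immune sample);
    sample S2 carries the active-T-exhaustion and CAF-differentiation
    trajectory endpoints.  Every sample has a scoring T-cell population with
    the tier-determining proliferation/suppression relation.
    """
    blocks = gene_layout(spec)
    base = _baseline_means(spec)
    cmeans = cluster_mean_matrix(spec)
    tiers = planted_tiers(spec)
    rng_t = spec.rng("tfactors")

    sup_idx = [blocks["genes"].index(g) for g in blocks["suppression"]]
    pro_idx = [blocks["genes"].index(g) for g in blocks["proliferation"]]

    mean_rows: list[np.ndarray] = []
    meta_rows: list[dict] = []

    def add_cell(mu: np.ndarray, sample: str, cell_type: str,
                 malignant: bool) -> None:
        mean_rows.append(mu)
        meta_rows.append({
            "cell_id": f"C{len(meta_rows) + 1:05d}", "sample_id": sample,
            "cell_type": cell_type, "is_malignant": malignant,
        })

    def t_cell_mean(sample: str) -> np.ndarray:
        # tier-determining relation: middle tiers have proliferation falling
        # with the suppressive signal (negative slope -> positive score)
        f = 2.0 ** rng_t.uniform(-2.0, 2.0)
        slope_sign = 1.0 if tiers[sample] == "low" else -1.0
        mu = base.to_numpy(dtype=float).copy()
        mu[sup_idx] *= f
        mu[pro_idx] *= f ** (1.5 * slope_sign)
        return mu

    # malignant clusters in S1
    for c in range(spec.n_clusters):
        mu_c = cmeans.loc[c].to_numpy(dtype=float)
        for _ in range(spec.cells_per_cluster):
            add_cell(mu_c, "S1", "Malignant", True)
    # scoring T cells in every sample
    for s in range(spec.n_samples):
        sample = f"S{s + 1}"
        for _ in range(spec.t_cells_per_sample):
            add_cell(t_cell_mean(sample), sample, "T cell", False)
    # trajectory endpoints in S2 (a middle-tier sample)
    if spec.n_samples >= 2:
        traj_genes = blocks["trajectory"]
        exhausted_boost = np.ones(spec.n_genes)
        for g in traj_genes["active_t_exhaustion"]:
            exhausted_boost[blocks["genes"].index(g)] = spec.deg_fold
        caf_boost = np.ones(spec.n_genes)
        for g in traj_genes["caf_differentiation"]:
            caf_boost[blocks["genes"].index(g)] = spec.deg_fold
        for _ in range(30):
            add_cell(t_cell_mean("S2"), "S2", "T_active", False)
        for _ in range(25):
            add_cell(t_cell_mean("S2") * exhausted_boost, "S2",
                     "T_exhausted", False)
        fibro = base.to_numpy(dtype=float)
        for _ in range(30):
            add_cell(fibro, "S2", "Fibroblast", False)
        for _ in range(25):
            add_cell(fibro * caf_boost, "S2", "CAF", False)

    mu = np.vstack(mean_rows)
    counts = _sample_counts(spec.rng("counts"), mu, spec.dispersion,
                            spec.dropout_rate)
    meta = pd.DataFrame(meta_rows)
    m = ExpressionMatrix(
        cell_ids=meta["cell_id"].to_numpy(dtype=object),
        gene_ids=np.asarray(blocks["genes"], dtype=object),
        counts=counts,
    )
    return m, meta


def simulate_reference_panel(spec: FixtureSpec) -> ReferencePanel:
    """Panel whose first lines match the planted clusters.

    Line c's profile is the log-normalised mean of planted cluster c plus
    Gaussian noise (sd ``panel_noise_sd``); remaining lines are unrelated.
    The sensitivity matrix realises the planted cluster -> drug map with
    sensitive entries at 0.95 and background entries near 0.05.
    """
    blocks = gene_layout(spec)
    rng = spec.rng("panel")
    cmeans = cluster_mean_matrix(spec)

    def lognorm(mu: np.ndarray) -> np.ndarray:
        cpm = mu / mu.sum() * 1e6
        return np.log2(cpm / 10.0 + 1.0)

    profiles = []
    for c in range(spec.n_clusters):
        prof = lognorm(cmeans.loc[c].to_numpy(dtype=float))
        profiles.append(prof + rng.normal(0.0, spec.panel_noise_sd,
                                          size=spec.n_genes))
    for _ in range(spec.n_lines - spec.n_clusters):
        random_mu = rng.gamma(2.0, 1.5, size=spec.n_genes)
        profiles.append(lognorm(random_mu))
    line_ids = [f"LINE_{i + 1}" for i in range(spec.n_lines)]
    prof_df = pd.DataFrame(np.clip(profiles, 0.0, None), index=line_ids,
                           columns=blocks["genes"])

    drug_ids = [_drug_name(i) for i in range(spec.n_drugs)]
    sens = pd.DataFrame(
        rng.uniform(0.02, 0.08, size=(spec.n_lines, spec.n_drugs)),
        index=line_ids, columns=drug_ids,
    )
    for cluster, drug in spec.planted_sensitivity.items():
        if drug not in drug_ids:
            raise ValidationError(f"planted drug {drug!r} outside the panel")
        sens.loc[f"LINE_{cluster + 1}", drug] = 0.95
    return ReferencePanel(profiles=prof_df, sensitivity=sens)


def simulate_signatures_and_side_effects(
        spec: FixtureSpec) -> tuple[SignatureLibrary, pd.DataFrame]:
    """Signature library with exact reversers plus the toxicity boundary pair.

    For each trajectory a drug ``REV_<TRAJECTORY>`` carries -1 on that
    trajectory's planted up-genes (a perfect reverser); decoys carry random
    signs on background genes.  TOX_HIGH has 12 side effects at 40%
    frequency (indicator 1) and TOX_LOW has 10 (indicator 0).
    """
    blocks = gene_layout(spec)
    rng = spec.rng("signatures")
    rows = {}
    for name, genes in blocks["trajectory"].items():
        sig = pd.Series(0.0, index=blocks["genes"])
        sig[genes] = -1.0
        rows[f"REV_{name.upper()}"] = sig
    for d in range(3):  # decoys on background genes
        sig = pd.Series(0.0, index=blocks["genes"])
        picked = rng.choice(blocks["background"], size=10, replace=False)
        sig[picked] = rng.choice([-1.0, 1.0], size=10)
        rows[f"DECOY_{d + 1}"] = sig
    lib = SignatureLibrary(signatures=pd.DataFrame(rows).T)

    se_rows = []
    for i in range(12):
        se_rows.append({"drug": "TOX_HIGH", "effect": f"E{i + 1}",
                        "frequency": 0.4})
    for i in range(10):
        se_rows.append({"drug": "TOX_LOW", "effect": f"E{i + 1}",
                        "frequency": 0.4})
    return lib, pd.DataFrame(se_rows)


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    matrix: ExpressionMatrix
    meta: pd.DataFrame
    panel: ReferencePanel
    library: SignatureLibrary
    side_effects: pd.DataFrame
    suppression: SignatureSet
    proliferation: SignatureSet
    truth: dict = field(default_factory=dict)


def default_fixture(seed: int = 0, **overrides) -> FixtureBundle:
    """Generate the complete default fixture with its planted ground truth."""
    spec = FixtureSpec(seed=seed, **overrides)
    m, meta = simulate_scrna(spec)
    panel = simulate_reference_panel(spec)
    lib, side_effects = simulate_signatures_and_side_effects(spec)
    sup, pro = immune_signatures(spec)
    truth = {
        "tiers": planted_tiers(spec),
        "n_malignant_clusters": spec.n_clusters,
        "combo": tuple(sorted(spec.planted_sensitivity.values())),
        "malignant_sample": "S1",
        "trajectory_sample": "S2",
        "reversers": {name: f"REV_{name.upper()}"
                      for name in ("active_t_exhaustion",
                                   "caf_differentiation")},
    }
    return FixtureBundle(spec=spec, matrix=m, meta=meta, panel=panel,
                         library=lib, side_effects=side_effects,
                         suppression=sup, proliferation=pro, truth=truth)
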