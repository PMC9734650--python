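"""Seeded synthetic count-matrix generator for end-to-end pipeline testing.

Emulates the statistical structure of paired unspliced/spliced single-cell
count matrices from replicated animals: each gene has fixed kinetic
parameters shared by all replicates, with counts sampled independently per
replicate by the hybrid stochastic simulator.  Regime-planted genes sit
deep inside the bursty (gamma-OU), heavy-tailed (CIR) and mixture corners
of the qualitative-regime square, and a handful of constructed genes
deliberately violate each expression-filter rule.

The generator does NOT emulate technical noise (dropout, ambient RNA,
barcode errors) or cell-to-cell coupling; what passes on these fixtures
demonstrates the statistical machinery, not robustness to measurement
artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .models import ModelKind, ModelParams, ParamValidationError, params_from_regime
from .inference import PMFCache, sample_dataset
from .pipeline import GeneTable, write_count_matrices
from .simulate import CountData, SimProtocol, simulate_cells

__all__ = ["FixtureSpec", "generate_fixture", "generate_insilico_bayes_data"]

#: regime-corner boxes (reversion_coord, gain_coord ranges) per category
REGIME_CORNERS = {
    "GOU-like": (ModelKind.GOU, (0.75, 0.9), (0.8, 0.92)),
    "CIR-like": (ModelKind.CIR, (0.75, 0.9), (0.8, 0.92)),
    "mixture-like": (ModelKind.GOU, (0.01, 0.03), (0.65, 0.85)),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Specification of a synthetic multi-replicate fixture.

    n_genes_per_regime genes are planted per regime corner; n_cells cells
    per replicate ("animal"); replicates share gene-level ground truth and
    differ only by RNG stream.  Defaults use the splicing/degradation rates
    of the simulator validation protocol (beta = 1.2, gamma = 0.7) and
    moderate expression so counts stay in the tractable range.
    """

    n_genes_per_regime: int = 6
    n_cells: int = 1000
    n_animals: int = 4
    n_subtypes: int = 2
    beta: float = 1.2
    gamma_: float = 0.7
    mean_rate_range: tuple = (3.0, 8.0)
    seed: int = 0
    include_filter_violations: bool = True

    def __post_init__(self):
        if self.n_genes_per_regime < 1 or self.n_cells < 1 or self.n_animals < 1:
            raise ParamValidationError("fixture sizes must be positive")


def _plant_gene_params(spec: FixtureSpec, rng: np.random.Generator):
    """Draw ground-truth parameters for every regime-planted gene."""
    genes = []
    for label, (kind, r_rng, g_rng) in REGIME_CORNERS.items():
        for i in range(spec.n_genes_per_regime):
            r = rng.uniform(*r_rng)
            g = rng.uniform(*g_rng)
            K = np.exp(rng.uniform(*np.log(spec.mean_rate_range)))
            p = params_from_regime(r, g, K, spec.beta, spec.gamma_)
            genes.append({
                "gene": f"{label.split('-')[0].lower()}_{i:02d}",
                "model": kind,
                "regime_label": label,
                "params": p,
            })
    return genes


def _violation_counts(kind: str, n_cells: int, rng: np.random.Generator):
    """Constructed (not simulated) count vectors triggering one filter rule."""
    n = np.zeros(n_cells, dtype=np.int64)
    m = rng.poisson(1.0, n_cells) + 1  # keep the other species unremarkable
    if kind == "low_mean":
        n[0] = 4  # mean 4/n_cells <= 0.01, max above the low-max bound
    elif kind == "low_max":
        n = rng.integers(0, 3, n_cells)  # mean ~1 > 0.01 but max <= 3
        n[0] = 2
    elif kind == "high_max":
        n = rng.poisson(2.0, n_cells)
        n[0] = 450  # max >= 400
    else:
        raise ParamValidationError(f"unknown violation kind {kind!r}")
    return n, m


def generate_fixture(spec: FixtureSpec, out_dir=None):
    """Generate the fixture; returns (GeneTable, ground_truth DataFrame).

    If out_dir is given, also writes nascent.mtx / mature.mtx / genes.tsv /
    cells.tsv / ground_truth.csv there.  Byte-identical for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    planted = _plant_gene_params(spec, rng)
    n_total_cells = spec.n_cells * spec.n_animals
    gene_rows = []
    nascent_rows = []
    mature_rows = []
    truth_rows = []
    for gi, g in enumerate(planted):
        xn = np.empty(n_total_cells, dtype=np.int64)
        xm = np.empty(n_total_cells, dtype=np.int64)
        for animal in range(spec.n_animals):
            proto = SimProtocol(
                n_reps=spec.n_cells,
                seed=int(spec.seed + 100003 * gi + 211 * animal + 1),
            )
            cd = simulate_cells(g["model"], g["params"], proto)
            sl = slice(animal * spec.n_cells, (animal + 1) * spec.n_cells)
            xn[sl] = cd.nascent
            xm[sl] = cd.mature
        gene_rows.append(g["gene"])
        nascent_rows.append(xn)
        mature_rows.append(xm)
        p = g["params"]
        truth_rows.append({
            "gene": g["gene"], "model": g["model"].value,
            "kappa": p.kappa, "theta": p.theta, "a": p.a,
            "beta": p.beta, "gamma": p.gamma_,
            "regime_label": g["regime_label"],
        })
    if spec.include_filter_violations:
        for kind in ("low_mean", "low_max", "high_max"):
            n, m = _violation_counts(kind, n_total_cells, rng)
            gene_rows.append(f"filter_{kind}")
            nascent_rows.append(n)
            mature_rows.append(m)
            truth_rows.append({
                "gene": f"filter_{kind}", "model": "none",
                "kappa": np.nan, "theta": np.nan, "a": np.nan,
                "beta": np.nan, "gamma": np.nan,
                "regime_label": f"filter_{kind}",
            })
    animals = np.repeat(
        [f"animal_{i}" for i in range(spec.n_animals)], spec.n_cells
    )
    subtypes = np.array([
        f"subtype_{i % spec.n_subtypes}" for i in range(n_total_cells)
    ])
    cells = pd.DataFrame({
        "cell_id": [f"cell_{i:06d}" for i in range(n_total_cells)],
        "animal": animals,
        "subtype": subtypes,
    })
    gt = GeneTable(
        gene_ids=gene_rows,
        nascent=np.vstack(nascent_rows),
        mature=np.vstack(mature_rows),
        cells=cells,
    )
    truth = pd.DataFrame(truth_rows)
    if out_dir is not None:
        paths = write_count_matrices(gt, out_dir)
        truth.to_csv(Path(out_dir) / "ground_truth.csv", index=False)
        paths["ground_truth"] = Path(out_dir) / "ground_truth.csv"
    return gt, truth


def generate_insilico_bayes_data(
    lattice,
    ground_truth_model: ModelKind,
    cells: int,
    n_datasets: int,
    seed: int = 0,
    mean_rate: float = 10.0,
    beta: float = 1.0,
    gamma_: float = 1.7,
    cache: PMFCache | None = None,
):
    """Inputs of the distinguishability experiment at configurable scale.

    For each regime-lattice point, n_datasets synthetic datasets of `cells`
    cells are sampled from the ground-truth model's exact steady-state PMF.
    Returns a list of {"coords", "params", "datasets": [CountData, ...]}.
    """
    if cells <= 0:
        raise ParamValidationError("cells must be positive")
    cache = cache if cache is not None else PMFCache()
    rng = np.random.default_rng(seed)
    out = []
    for rc in lattice:
        p = params_from_regime(
            rc.reversion_coord, rc.gain_coord, mean_rate, beta, gamma_
        )
        datasets = [
            sample_dataset(ground_truth_model, p, cells, rng, cache)
            for _ in range(n_datasets)
        ]
        out.append({"coords": rc, "params": p, "datasets": datasets})
    return out
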