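"""Synthetic multi-dataset single-cell count generator with known truth.

The generator emulates the statistical structure the analysis modules
assume: several datasets of sparse non-negative integer counts, each with
a minority marker-positive population (OPC-like cells detectable through
a marker gene), a 19-gene subunit panel whose within-cell counts follow
cell-type mixing proportions (jittered per dataset), lognormal
library-size variation, Bernoulli dropout, planted co-expressed
"scaffold" genes tracking the summed panel signal, and independent
low-rate background genes.

Generative model, per cell:

1. cell type: marker-positive type with probability ``marker_positive_rate``,
   otherwise uniformly one of the remaining types;
2. library factor ``L ~ LogNormal(mu, sigma)``;
3. panel total ``N ~ Poisson(mean_panel_counts * L)``;
4. panel counts ``Multinomial(N, p)`` where ``p`` is the dataset-level
   proportion vector: drawn once per (dataset, type) as
   ``Dirichlet(kappa * p_type)`` around the type's base proportions
   (``kappa = None`` disables jitter);
5. each panel entry zeroed independently with ``dropout_prob``;
6. the cell's type marker gene receives ``1 + Poisson(1)`` counts
   (other types' markers stay 0);
7. planted correlates: ``max(0, round(panel_sum + N(0, noise_sd)))``
   using the observed (post-dropout) panel sum;
8. background genes: ``Poisson(lambda_g * L)`` with per-gene rates
   ``lambda_g ~ Exponential(background_rate)`` drawn once per dataset.

Each dataset derives its RNG stream from ``(seed, dataset_index)``, so
adding a dataset never perturbs the ones before it, and a fixed seed
reproduces matrices bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import scipy.integrate
import scipy.stats
import yaml

from .errors import ValidationError
from .matrix import AGE_GROUPS, ExpressionMatrix, Unit
from .panel import PANEL_SIZE, SubunitPanel, default_panel


@dataclass
class CellTypeSpec:
    """One simulated cell type: marker gene plus panel mixing proportions."""

    name: str
    marker_gene: str
    panel_proportions: list[float]
    mean_panel_counts: float = 200.0

    def __post_init__(self) -> None:
        p = np.asarray(self.panel_proportions, dtype=float)
        if p.shape != (PANEL_SIZE,):
            raise ValidationError(
                f"cell type {self.name}: panel_proportions must have "
                f"{PANEL_SIZE} entries"
            )
        if (p < 0).any():
            raise ValidationError(f"cell type {self.name}: negative proportion")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValidationError(
                f"cell type {self.name}: proportions sum to {p.sum()!r}, not 1"
            )
        if not self.mean_panel_counts > 0:
            raise ValidationError(f"cell type {self.name}: mean_panel_counts <= 0")
        self.panel_proportions = [float(v) for v in p]


@dataclass
class PlantedCorrelate:
    """A gene tracking the per-cell panel sum plus Gaussian noise."""

    symbol: str
    noise_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError(f"{self.symbol}: noise_sd < 0")


@dataclass
class DatasetSpec:
    """One simulated dataset: size, age group and marker-positive rate."""

    dataset_id: str
    n_cells: int
    age_group: str = "adult"
    marker_positive_rate: float = 0.12
    proportion_overrides: dict[str, list[float]] | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValidationError(f"{self.dataset_id}: n_cells < 1")
        if not 0 < self.marker_positive_rate < 1:
            raise ValidationError(
                f"{self.dataset_id}: marker_positive_rate must be in (0,1)"
            )
        if self.age_group not in AGE_GROUPS:
            raise ValidationError(
                f"{self.dataset_id}: age_group {self.age_group!r} not in {AGE_GROUPS}"
            )


@dataclass
class SyntheticTruth:
    """Full generative configuration (the ground truth for recovery tests).

    Defaults describe a realistic droplet experiment: ~12% marker-positive
    cells, moderate library-size spread (lognormal sigma 0.3), mild
    dropout, and a few thousand background genes at low Poisson rates.
    """

    seed: int
    datasets: list[DatasetSpec]
    cell_types: list[CellTypeSpec]
    library_mu: float = 0.0
    library_sigma: float = 0.3
    dropout_prob: float = 0.1
    n_background_genes: int = 200
    background_rate: float = 0.1
    planted_correlates: list[PlantedCorrelate] = field(default_factory=list)
    kappa: float | None = 50.0   # Dirichlet concentration; None = no jitter
    unit: str = "UMI"

    def __post_init__(self) -> None:
        self.datasets = [
            d if isinstance(d, DatasetSpec) else DatasetSpec(**d) for d in self.datasets
        ]
        self.cell_types = [
            c if isinstance(c, CellTypeSpec) else CellTypeSpec(**c)
            for c in self.cell_types
        ]
        self.planted_correlates = [
            p if isinstance(p, PlantedCorrelate) else PlantedCorrelate(**p)
            for p in self.planted_correlates
        ]
        if not self.datasets:
            raise ValidationError("at least one dataset required")
        if not self.cell_types:
            raise ValidationError("at least one cell type required")
        ids = [d.dataset_id for d in self.datasets]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate dataset_id in truth")
        if not 0 <= self.dropout_prob < 1:
            raise ValidationError("dropout_prob must be in [0, 1)")
        if self.library_sigma < 0:
            raise ValidationError("library_sigma < 0")
        if self.kappa is not None and not self.kappa > 0:
            raise ValidationError("kappa must be positive or None")
        if self.n_background_genes < 0:
            raise ValidationError("n_background_genes < 0")
        if Unit(self.unit) not in (Unit.UMI, Unit.FPKM):
            raise ValidationError("unit must be UMI or FPKM")
        for d in self.datasets:
            for name in (d.proportion_overrides or {}):
                if name not in {c.name for c in self.cell_types}:
                    raise ValidationError(
                        f"{d.dataset_id}: override for unknown cell type {name!r}"
                    )
                CellTypeSpec(  # reuse its validation
                    name=name, marker_gene="x",
                    panel_proportions=d.proportion_overrides[name],
                )

    # -- YAML round trip ------------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


@dataclass
class DatasetTruthRecord:
    """Realised per-dataset generative state for recovery tests."""

    dataset_id: str
    age_group: str
    proportions: dict[str, list[float]]   # dataset-level, per cell type
    type_counts: dict[str, int]
    n_marker_positive: int
    seed_stream: tuple[int, int]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _dirichlet_jitter(rng: np.random.Generator, p: np.ndarray,
                      kappa: float | None) -> np.ndarray:
    """Dirichlet(kappa * p) supported on the positive components of p."""
    if kappa is None:
        return p.copy()
    out = np.zeros_like(p)
    pos = p > 0
    if pos.sum() == 1:
        out[pos] = 1.0
        return out
    out[pos] = rng.dirichlet(kappa * p[pos])
    return out


def gene_order(truth: SyntheticTruth) -> list[str]:
    """Panel genes, then marker genes, planted correlates, background."""
    panel = default_panel().genes
    markers = [c.marker_gene for c in truth.cell_types if c.marker_gene not in panel]
    seen = set(panel)
    uniq_markers = [m for m in markers if not (m in seen or seen.add(m))]
    planted = [p.symbol for p in truth.planted_correlates]
    width = max(4, len(str(max(truth.n_background_genes - 1, 0))))
    background = [f"BG{i:0{width}d}" for i in range(truth.n_background_genes)]
    return panel + uniq_markers + planted + background


def simulate_dataset(
    truth: SyntheticTruth, dataset_id: str
) -> tuple[ExpressionMatrix, DatasetTruthRecord]:
    """Generate one dataset of the truth configuration.

    Deterministic: the RNG stream is seeded from ``(truth.seed, index of
    the dataset in the truth)``, independent of the other datasets.
    """
    ids = [d.dataset_id for d in truth.datasets]
    if dataset_id not in ids:
        raise ValidationError(f"dataset {dataset_id!r} not in truth")
    ds_index = ids.index(dataset_id)
    spec = truth.datasets[ds_index]
    rng = np.random.default_rng(np.random.SeedSequence((truth.seed, ds_index)))

    panel = default_panel()
    symbols = gene_order(truth)
    col = {g: j for j, g in enumerate(symbols)}
    n = spec.n_cells
    n_types = len(truth.cell_types)

    # dataset-level proportions, one Dirichlet draw per cell type
    ds_props: dict[str, np.ndarray] = {}
    for ct in truth.cell_types:
        base = np.asarray(
            (spec.proportion_overrides or {}).get(ct.name, ct.panel_proportions),
            dtype=float,
        )
        ds_props[ct.name] = _dirichlet_jitter(rng, base, truth.kappa)

    # cell type assignment: marker-positive type is cell_types[0]
    is_pos = rng.random(n) < spec.marker_positive_rate
    type_idx = np.zeros(n, dtype=int)
    if n_types > 1:
        type_idx[~is_pos] = rng.integers(1, n_types, size=(~is_pos).sum())
    else:
        type_idx[:] = 0

    lib = rng.lognormal(truth.library_mu, truth.library_sigma, size=n)

    values = np.zeros((n, len(symbols)), dtype=float)
    panel_cols = np.array([col[g] for g in panel.genes])
    for t, ct in enumerate(truth.cell_types):
        cells = np.flatnonzero(type_idx == t)
        if cells.size == 0:
            continue
        totals = rng.poisson(ct.mean_panel_counts * lib[cells])
        counts = rng.multinomial(totals, ds_props[ct.name])
        values[np.ix_(cells, panel_cols)] = counts
        # marker positivity is deterministic for the type (>= 1 count)
        values[cells, col[ct.marker_gene]] += 1 + rng.poisson(1.0, size=cells.size)

    if truth.dropout_prob > 0:
        drop = rng.random((n, PANEL_SIZE)) < truth.dropout_prob
        values[:, panel_cols] = np.where(drop, 0.0, values[:, panel_cols])

    response = values[:, panel_cols].sum(axis=1)
    for pc in truth.planted_correlates:
        noise = rng.normal(0.0, pc.noise_sd, size=n) if pc.noise_sd > 0 else 0.0
        values[:, col[pc.symbol]] = np.maximum(0.0, np.rint(response + noise))

    if truth.n_background_genes:
        lam = rng.exponential(truth.background_rate, size=truth.n_background_genes)
        bg0 = len(symbols) - truth.n_background_genes
        values[:, bg0:] = rng.poisson(lam[None, :] * lib[:, None])

    unit = Unit(truth.unit)
    if unit is Unit.FPKM:
        # length-normalised continuous mode: per-gene scale factors
        lengths = rng.uniform(0.5, 3.0, size=len(symbols))
        values = values * lengths[None, :]

    import pandas as pd

    cell_ids = [f"{dataset_id}:cell{i:05d}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "age_group": spec.age_group,
            "cell_type_label": [truth.cell_types[t].name for t in type_idx],
            "mito_fraction": 0.0,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    m = ExpressionMatrix(
        dataset_id=dataset_id,
        cell_ids=cell_ids,
        gene_symbols=symbols,
        values=values,
        unit=unit,
        cell_meta=meta,
    )
    record = DatasetTruthRecord(
        dataset_id=dataset_id,
        age_group=spec.age_group,
        proportions={k: v.tolist() for k, v in ds_props.items()},
        type_counts={
            ct.name: int((type_idx == t).sum())
            for t, ct in enumerate(truth.cell_types)
        },
        n_marker_positive=int(
            (type_idx == 0).sum() if n_types > 1 else n
        ),
        seed_stream=(truth.seed, ds_index),
    )
    return m, record


def simulate_multi(
    truth: SyntheticTruth,
) -> list[tuple[ExpressionMatrix, DatasetTruthRecord]]:
    """Generate every dataset in the truth, each from its own stream."""
    return [simulate_dataset(truth, d.dataset_id) for d in truth.datasets]


def expected_detection_prob(
    truth: SyntheticTruth, cell_type: str | None = None
) -> np.ndarray:
    """Model-implied per-panel-gene detection probability (FC3 / 100).

    A gene with mixing proportion ``p`` has marginal count
    ``Poisson(mean_panel_counts * L * p)`` (Poisson thinning of the
    multinomial), so its zero probability is
    ``E_L[exp(-mean * p * L)]`` over the lognormal library factor, and
    detection is ``(1 - dropout_prob) * (1 - P0)``.  Computed by
    numerical integration; assumes no Dirichlet jitter (kappa None).
    """
    ct = (
        truth.cell_types[0]
        if cell_type is None
        else next(c for c in truth.cell_types if c.name == cell_type)
    )
    p = np.asarray(ct.panel_proportions, dtype=float)
    mean = ct.mean_panel_counts
    mu, sigma = truth.library_mu, truth.library_sigma

    def p_zero(rate: float) -> float:
        if rate == 0:
            return 1.0
        if sigma == 0:
            return float(np.exp(-rate * np.exp(mu)))
        dist = scipy.stats.lognorm(s=sigma, scale=np.exp(mu))
        val, _ = scipy.integrate.quad(
            lambda l: np.exp(-rate * l) * dist.pdf(l), 0, np.inf, limit=200
        )
        return float(val)

    p0 = np.array([p_zero(mean * pg) for pg in p])
    return (1.0 - truth.dropout_prob) * (1.0 - p0)


def write_simulated(
    truth: SyntheticTruth, out_dir: str | Path
) -> list[Path]:
    """Simulate every dataset and write MTX triplets + truth sidecars."""
    from .io import write_mtx_triplet

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for m, record in simulate_multi(truth):
        ds_dir = out / m.dataset_id
        write_mtx_triplet(m, ds_dir)
        record.to_json(ds_dir / "truth.json")
        paths.append(ds_dir)
    truth.to_yaml(out / "truth.yaml")
    return paths
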