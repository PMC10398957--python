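"""Synthetic single-nucleus RNA-seq cohorts with a planted reactivity axis.

The generator emulates a 15-donor frontal-cortex astrocyte study: donors
vary in binary amyloid/tau pathology and APOE / TREM2 genotype; nuclei
fall into four populations (protoplasmic astrocytes, fibrous astrocytes,
astrocyte-neuron doublets, astrocyte-oligodendrocyte doublets) in roughly
the proportions such datasets show. Protoplasmic nuclei carry a latent
reactivity score r in [0, 1]; a configurable set of genes is planted to
increase (default 52) or decrease (default 144) log-linearly with r, and
amyloid-positive donors have a higher mean r (default shift 0.118, with
donor-level random intercepts). Counts are negative-binomial with
per-gene dispersion; doublets are sums of two parent profiles thinned
back to singlet depth. Everything is reproducible from the config seed,
and the ground truth (per-nucleus r, populations, doublet parents,
per-gene direction) is returned alongside the counts for recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountMatrix, write_mtx_dir
from .enrichment import SignatureSet

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "simulate_dataset",
    "make_doublets",
    "truth_signature",
    "simulate_reactivity_cohort",
    "write_dataset",
    "DEFAULT_MARKER_PANELS",
    "HOMEOSTATIC_PANEL",
    "microglia_preset",
]

# Marker panels are simulated as population-specific high-mean genes; the
# symbols are labels borrowed from the astrocyte/neuron/oligodendrocyte
# literature so that downstream annotation configs read naturally.
DEFAULT_MARKER_PANELS: dict[str, list[str]] = {
    "protoplasmic": ["SLC1A2", "SLC1A3", "GLUL", "AQP4", "GJA1", "SLC6A11", "ATP1A2", "MERTK"],
    "fibrous": ["GFAP", "CD44", "TNC", "AQP1", "ARHGEF4", "S100B", "CRYAB", "ID3"],
    "neuron": ["RBFOX3", "SNAP25", "SYT1", "NRGN", "SLC17A7", "GAD1", "STMN2", "THY1"],
    "oligo": ["PLP1", "MBP", "MOBP", "MOG", "CNP", "MAG", "CLDN11", "ST18"],
}

#: labels given to the first planted genes so the root-selection rule
#: ("homeostatic expression highest at the start of the trajectory") has
#: named genes to score; all four are planted as downregulated.
HOMEOSTATIC_PANEL = ["NRXN1", "NRG3", "GPC5", "ERBB4"]
_UP_LABELS = ["VIM", "CHI3L1", "SERPINA3", "CP"]
_DOWN_LABELS = HOMEOSTATIC_PANEL + ["NFIA", "KCNIP4"]

_SINGLET_POPULATIONS = ("protoplasmic", "fibrous")
_DOUBLET_SPECS = {"doublet_neuron": "neuron", "doublet_oligo": "oligo"}


@dataclass
class SimulationConfig:
    """Study-design and noise parameters for one synthetic cohort.

    Defaults mirror a 15-donor cohort (10 amyloid-positive, of which 5
    also tau-positive) with population sizes at one fifth of the
    reference astrocyte dataset's 7153/4184/2161/2031 split.
    """

    n_samples: int = 15
    amyloid_positive: int = 10
    tau_positive: int = 5
    apoe_freqs: dict[str, float] = field(
        default_factory=lambda: {"E3/E3": 0.6, "E3/E4": 0.3, "E4/E4": 0.1}
    )
    trem2_freqs: dict[str, float] = field(default_factory=lambda: {"WT": 0.85, "R47H": 0.15})
    nuclei_per_type: dict[str, int] = field(
        default_factory=lambda: {
            "protoplasmic": 1430,
            "fibrous": 837,
            "doublet_neuron": 432,
            "doublet_oligo": 406,
        }
    )
    n_genes: int = 2000
    n_up: int = 52
    n_down: int = 144
    slope_up: float = 0.3
    slope_down: float = -0.5
    baseline_log_mean: tuple[float, float] = (-1.5, 1.0)
    planted_log_mean: tuple[float, float] = (1.0, 0.5)
    marker_log_mean: tuple[float, float] = (-0.5, 0.5)
    marker_boost: float = 3.0
    nb_dispersion: float = 10.0
    dispersion_sigma: float = 0.5
    depth_mean: float = 5000.0
    depth_sigma: float = 0.3
    amyloid_shift: float = 0.118
    donor_sd: float = 0.05
    marker_panels: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_MARKER_PANELS.items()}
    )
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_samples", "n_genes", "n_up", "n_down"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.tau_positive <= self.amyloid_positive <= self.n_samples):
            raise ValueError(
                "require 0 <= tau_positive <= amyloid_positive <= n_samples "
                f"(got tau_positive={self.tau_positive}, "
                f"amyloid_positive={self.amyloid_positive}, n_samples={self.n_samples})"
            )
        for name, freqs in (("apoe_freqs", self.apoe_freqs), ("trem2_freqs", self.trem2_freqs)):
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities must sum to 1")
            if any(p < 0 for p in freqs.values()):
                raise ValueError(f"{name} probabilities must be >= 0")
        for pop, n in self.nuclei_per_type.items():
            if n < 0:
                raise ValueError(f"nuclei_per_type[{pop!r}] must be >= 0")
        unknown = set(self.nuclei_per_type) - set(_SINGLET_POPULATIONS) - set(_DOUBLET_SPECS)
        if unknown:
            raise ValueError(f"nuclei_per_type has unknown populations: {sorted(unknown)}")
        n_markers = sum(len(v) for v in self.marker_panels.values())
        if self.n_up + self.n_down + n_markers + 1 > self.n_genes:
            raise ValueError(
                "n_genes too small: need n_up + n_down + marker panels + MALAT1 "
                f"<= n_genes ({self.n_up}+{self.n_down}+{n_markers}+1 > {self.n_genes})"
            )
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Truth channel for recovery tests (never consumed by the pipeline).

    ``nuclei`` has one row per output nucleus (population, donor, latent
    r for protoplasmic nuclei and NaN elsewhere, doublet parent IDs);
    ``genes`` has one row per gene (direction up/down/null/marker and
    the planted log-scale slope per unit reactivity).
    """

    nuclei: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        is_proto = self.nuclei["population"] == "protoplasmic"
        if self.nuclei.loc[is_proto, "r"].isna().any():
            raise ValueError("protoplasmic nuclei must have latent r defined")
        if self.nuclei.loc[~is_proto, "r"].notna().any():
            raise ValueError("latent r is defined only for protoplasmic nuclei")


@dataclass
class SyntheticDataset:
    counts: CountMatrix
    meta: pd.DataFrame
    truth: GroundTruth

    def __post_init__(self) -> None:
        n = self.counts.n_nuclei
        if len(self.meta) != n or len(self.truth.nuclei) != n:
            raise ValueError("counts, metadata and truth must have one row per nucleus")


def _make_donor_table(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Donor covariates: tau-positive donors are a subset of amyloid-positive."""
    n = config.n_samples
    samples = [f"S{i + 1:02d}" for i in range(n)]
    amyloid = np.zeros(n, dtype=int)
    tau = np.zeros(n, dtype=int)
    amyloid[: config.amyloid_positive] = 1
    tau[: config.tau_positive] = 1
    apoe = rng.choice(list(config.apoe_freqs), size=n, p=list(config.apoe_freqs.values()))
    trem2 = rng.choice(list(config.trem2_freqs), size=n, p=list(config.trem2_freqs.values()))
    age = rng.integers(65, 96, size=n)
    return pd.DataFrame(
        {"sample": samples, "amyloid": amyloid, "tau": tau, "apoe": apoe, "trem2": trem2, "age": age}
    )


def _draw_reactivity(
    donor_idx: np.ndarray,
    donors: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Latent r: Beta(2,2) base + donor intercept +/- half the amyloid shift."""
    u = rng.normal(0.0, config.donor_sd, size=len(donors))
    base = rng.beta(2.0, 2.0, size=len(donor_idx))
    shift = config.amyloid_shift * (donors["amyloid"].to_numpy()[donor_idx] - 0.5)
    return np.clip(base + u[donor_idx] + shift, 0.0, 1.0)


def simulate_reactivity_cohort(
    config: SimulationConfig,
    nuclei_per_donor: int,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Donor covariates plus per-nucleus latent reactivity, without counts.

    Convenience channel for exercising the donor-level statistics (e.g.
    the mixed model) at the generator's planted amyloid shift.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    donors = _make_donor_table(config, rng)
    donor_idx = np.repeat(np.arange(len(donors)), nuclei_per_donor)
    r = _draw_reactivity(donor_idx, donors, config, rng)
    out = donors.iloc[donor_idx].reset_index(drop=True)
    out.insert(0, "nucleus_id", [f"N{i:06d}" for i in range(len(out))])
    out["r"] = r
    return out


@dataclass
class _GeneModel:
    names: np.ndarray
    baseline: np.ndarray          # log relative mean
    slope: np.ndarray             # log change per unit r (protoplasmic only)
    theta: np.ndarray             # NB dispersion per gene
    direction: np.ndarray         # up / down / null / marker
    boosts: dict[str, np.ndarray]  # population -> additive log boost


def _build_gene_model(config: SimulationConfig, rng: np.random.Generator) -> _GeneModel:
    g = config.n_genes
    names: list[str] = []
    direction = np.array(["null"] * g, dtype=object)
    baseline = rng.normal(*config.baseline_log_mean, size=g)
    slope = np.zeros(g)
    boosts = {pop: np.zeros(g) for pop in list(_SINGLET_POPULATIONS) + ["neuron", "oligo"]}

    idx = 0
    for pop, panel in config.marker_panels.items():
        for gene in panel:
            names.append(gene)
            direction[idx] = "marker"
            baseline[idx] = rng.normal(*config.marker_log_mean)
            boosts[pop][idx] = config.marker_boost
            idx += 1
    names.append("MALAT1")
    baseline[idx] = 4.0  # very high nuclear transcript, flat along the trajectory
    idx += 1
    for i in range(config.n_up):
        names.append(_UP_LABELS[i] if i < len(_UP_LABELS) else f"RUP{i:04d}")
        direction[idx] = "up"
        baseline[idx] = rng.normal(*config.planted_log_mean)
        slope[idx] = config.slope_up
        idx += 1
    for i in range(config.n_down):
        names.append(_DOWN_LABELS[i] if i < len(_DOWN_LABELS) else f"RDN{i:04d}")
        direction[idx] = "down"
        baseline[idx] = rng.normal(*config.planted_log_mean)
        slope[idx] = config.slope_down
        idx += 1
    names.extend(f"G{i:05d}" for i in range(g - idx))

    theta = rng.lognormal(np.log(config.nb_dispersion), config.dispersion_sigma, size=g)
    return _GeneModel(np.array(names, dtype=object), baseline, slope, theta, direction, boosts)


def _nb_sample(mean: np.ndarray, theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Gamma-Poisson draw: var = mu + mu^2 / theta."""
    lam = rng.gamma(shape=theta, scale=mean / theta)
    return rng.poisson(lam)


def make_doublets(
    counts: CountMatrix,
    populations: np.ndarray,
    parents: tuple[str, str],
    n: int,
    rng: np.random.Generator,
    target_depth: float | None = None,
    thin: bool = True,
    id_prefix: str = "DBL",
) -> tuple[CountMatrix, pd.DataFrame]:
    """Append ``n`` doublets formed from two parent populations.

    Each doublet is the elementwise sum of one nucleus sampled (without
    replacement) from each parent population; with ``thin`` the summed
    vector is binomially thinned to ``target_depth`` so a doublet carries
    one droplet's library depth rather than two. Returns the input counts
    with doublet rows appended plus a flag table (nucleus_id, is_doublet,
    parent_a, parent_b).
    """
    populations = np.asarray(populations, dtype=object)
    if len(populations) != counts.n_nuclei:
        raise ValueError("populations must align with count rows")
    pop_a, pop_b = parents
    idx_a = np.flatnonzero(populations == pop_a)
    idx_b = np.flatnonzero(populations == pop_b)
    flags = pd.DataFrame(
        {
            "nucleus_id": counts.nucleus_ids,
            "is_doublet": False,
            "parent_a": pd.NA,
            "parent_b": pd.NA,
        }
    )
    if n == 0:
        return counts, flags
    if idx_a.size == 0 or idx_b.size == 0:
        raise ValueError(f"both parent populations must be present: {parents}")
    if n > min(idx_a.size, idx_b.size):
        raise ValueError(
            f"requested {n} doublets but only {min(idx_a.size, idx_b.size)} "
            f"disjoint ({pop_a}, {pop_b}) parent pairs are available"
        )
    pick_a = rng.choice(idx_a, size=n, replace=False)
    pick_b = rng.choice(idx_b, size=n, replace=False)
    dense = np.asarray(counts.values[pick_a].todense()) + np.asarray(
        counts.values[pick_b].todense()
    )
    if thin:
        if target_depth is None:
            target_depth = float(np.asarray(counts.values[idx_a].sum(axis=1)).mean())
        totals = dense.sum(axis=1, keepdims=True)
        p = np.minimum(1.0, target_depth / np.maximum(totals, 1))
        dense = rng.binomial(dense, np.broadcast_to(p, dense.shape))
    ids = np.array([f"{id_prefix}_{pop_a}_{pop_b}_{i:05d}" for i in range(n)], dtype=object)
    new_flags = pd.DataFrame(
        {
            "nucleus_id": ids,
            "is_doublet": True,
            "parent_a": counts.nucleus_ids[pick_a],
            "parent_b": counts.nucleus_ids[pick_b],
        }
    )
    out = CountMatrix(
        sp.vstack([counts.values, sp.csr_matrix(dense)]).tocsr(),
        counts.gene_ids,
        np.concatenate([counts.nucleus_ids, ids]),
    )
    return out, pd.concat([flags, new_flags], ignore_index=True)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw one full synthetic cohort with ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    donors = _make_donor_table(config, rng)
    model = _build_gene_model(config, rng)

    n_proto = config.nuclei_per_type.get("protoplasmic", 0)
    n_fib = config.nuclei_per_type.get("fibrous", 0)
    n_dbl = {pop: config.nuclei_per_type.get(pop, 0) for pop in _DOUBLET_SPECS}

    # --- latent reactivity and donor assignment for singlets
    donor_u = rng.normal(0.0, config.donor_sd, size=len(donors))
    amyloid = donors["amyloid"].to_numpy()

    def draw_r(donor_idx: np.ndarray) -> np.ndarray:
        base = rng.beta(2.0, 2.0, size=donor_idx.size)
        shift = config.amyloid_shift * (amyloid[donor_idx] - 0.5)
        return np.clip(base + donor_u[donor_idx] + shift, 0.0, 1.0)

    def simulate_block(
        population: str, count: int, with_r: bool
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
        donor_idx = rng.integers(0, len(donors), size=count)
        r = draw_r(donor_idx) if with_r else None
        mu_rel = (
            np.exp(model.baseline + model.boosts.get(population, 0.0))[None, :]
            * np.ones((count, 1))
            if r is None
            else np.exp(
                (model.baseline + model.boosts.get(population, 0.0))[None, :]
                + np.outer(r, model.slope)
            )
        )
        return donor_idx, mu_rel, r

    proto_donor, proto_mu, proto_r = simulate_block("protoplasmic", n_proto, True)
    fib_donor, fib_mu, _ = simulate_block("fibrous", n_fib, False)

    # calibrate relative means to the configured sequencing depth using the
    # astrocyte singlets, then apply per-nucleus lognormal depth factors
    rel_sums = np.concatenate([proto_mu.sum(axis=1), fib_mu.sum(axis=1)])
    scale = config.depth_mean / rel_sums.mean() if rel_sums.size else 1.0

    def sample_counts(mu_rel: np.ndarray) -> sp.csr_matrix:
        if mu_rel.shape[0] == 0:
            return sp.csr_matrix((0, config.n_genes), dtype=np.int64)
        depth = rng.lognormal(-config.depth_sigma**2 / 2, config.depth_sigma, mu_rel.shape[0])
        mu = scale * mu_rel * depth[:, None]
        return sp.csr_matrix(_nb_sample(mu, model.theta[None, :], rng))

    proto_counts = sample_counts(proto_mu)
    fib_counts = sample_counts(fib_mu)

    # --- hidden parent pools for doublets (astro + neuron/oligo profiles)
    hidden_parts: list[tuple[str, str, sp.csr_matrix, np.ndarray]] = []
    doublet_parent_pop: dict[str, np.ndarray] = {}
    for pop, other in _DOUBLET_SPECS.items():
        n = n_dbl[pop]
        if n == 0:
            continue
        astro_donor = rng.integers(0, len(donors), size=n)
        astro_kind = rng.choice(
            _SINGLET_POPULATIONS, size=n, p=_astro_mix(n_proto, n_fib)
        )
        r_h = draw_r(astro_donor)
        log_mu = model.baseline[None, :] + np.where(
            (astro_kind == "protoplasmic")[:, None],
            model.boosts["protoplasmic"][None, :] + np.outer(r_h, model.slope),
            model.boosts["fibrous"][None, :],
        )
        astro_mu = np.exp(log_mu)
        other_mu = np.exp(model.baseline + model.boosts[other])[None, :] * np.ones((n, 1))
        hidden_parts.append((pop, "astro", sample_counts(astro_mu), astro_donor))
        hidden_parts.append((pop, other, sample_counts(other_mu), astro_donor))
        doublet_parent_pop[pop] = astro_donor

    # --- build doublets from the hidden pools
    doublet_blocks: dict[str, tuple[sp.csr_matrix, pd.DataFrame, np.ndarray]] = {}
    for pop, other in _DOUBLET_SPECS.items():
        n = n_dbl[pop]
        if n == 0:
            continue
        astro_counts = next(c for p, kind, c, _ in hidden_parts if p == pop and kind == "astro")
        other_counts = next(c for p, kind, c, _ in hidden_parts if p == pop and kind == other)
        pool = CountMatrix(
            sp.vstack([astro_counts, other_counts]).tocsr(),
            model.names,
            np.array(
                [f"H_{pop}_astro_{i:05d}" for i in range(n)]
                + [f"H_{pop}_{other}_{i:05d}" for i in range(n)],
                dtype=object,
            ),
        )
        pool_pops = np.array(["astro"] * n + [other] * n, dtype=object)
        with_dbl, flags = make_doublets(
            pool, pool_pops, ("astro", other), n, rng,
            target_depth=scale * config.depth_mean, id_prefix=pop.upper(),
        )
        dbl_rows = flags["is_doublet"].to_numpy()
        dbl_counts = with_dbl.values[with_dbl.n_nuclei - n :]
        # donor of the doublet = donor of its astro parent
        parent_a = flags.loc[dbl_rows, "parent_a"].to_numpy()
        astro_order = np.array([int(p.rsplit("_", 1)[1]) for p in parent_a])
        dbl_donor = doublet_parent_pop[pop][astro_order]
        dbl_flags = flags.loc[dbl_rows, ["nucleus_id", "parent_a", "parent_b"]].reset_index(
            drop=True
        )
        doublet_blocks[pop] = (sp.csr_matrix(dbl_counts), dbl_flags, dbl_donor)

    # --- assemble outputs
    mats = [proto_counts, fib_counts]
    nucleus_ids = [f"P{i:06d}" for i in range(n_proto)] + [f"F{i:06d}" for i in range(n_fib)]
    pops = ["protoplasmic"] * n_proto + ["fibrous"] * n_fib
    donor_all = list(proto_donor) + list(fib_donor)
    r_all = list(proto_r) + [np.nan] * n_fib
    parent_a_all: list = [pd.NA] * (n_proto + n_fib)
    parent_b_all: list = [pd.NA] * (n_proto + n_fib)
    for pop in _DOUBLET_SPECS:
        if pop not in doublet_blocks:
            continue
        mat, flags, dbl_donor = doublet_blocks[pop]
        mats.append(mat)
        nucleus_ids.extend(flags["nucleus_id"])
        pops.extend([pop] * len(flags))
        donor_all.extend(dbl_donor)
        r_all.extend([np.nan] * len(flags))
        parent_a_all.extend(flags["parent_a"])
        parent_b_all.extend(flags["parent_b"])

    counts = CountMatrix(
        sp.vstack(mats).tocsr(), model.names, np.array(nucleus_ids, dtype=object)
    )
    donor_all = np.asarray(donor_all, dtype=int)
    meta = donors.iloc[donor_all].reset_index(drop=True)
    meta.insert(0, "nucleus_id", counts.nucleus_ids)
    truth_nuclei = pd.DataFrame(
        {
            "nucleus_id": counts.nucleus_ids,
            "population": pops,
            "sample": meta["sample"].to_numpy(),
            "r": r_all,
            "parent_a": parent_a_all,
            "parent_b": parent_b_all,
        }
    )
    truth_genes = pd.DataFrame(
        {"gene": model.names, "direction": model.direction, "true_slope": model.slope}
    )
    return SyntheticDataset(counts, meta, GroundTruth(truth_nuclei, truth_genes))


def _astro_mix(n_proto: int, n_fib: int) -> list[float]:
    total = n_proto + n_fib
    if total == 0:
        return [0.5, 0.5]
    return [n_proto / total, n_fib / total]


def truth_signature(truth: GroundTruth) -> SignatureSet:
    """Planted up/down gene lists for recovery scoring."""
    up = truth.genes.loc[truth.genes["direction"] == "up", "gene"].tolist()
    down = truth.genes.loc[truth.genes["direction"] == "down", "gene"].tolist()
    directions = {g: "up" for g in up} | {g: "down" for g in down}
    return SignatureSet(name="planted", genes=up + down, directions=directions)


def microglia_preset(seed: int = 0, n_nuclei: int = 2773, n_genes: int = 2000) -> SimulationConfig:
    """A second-cell-type preset: one population with a predominantly
    upregulated planted program, emulating an amyloid-responsive
    microglia trajectory at its reference size of 2773 nuclei."""
    return SimulationConfig(
        nuclei_per_type={"protoplasmic": n_nuclei, "fibrous": 0,
                         "doublet_neuron": 0, "doublet_oligo": 0},
        n_genes=n_genes,
        n_up=150,
        n_down=30,
        slope_up=0.6,
        slope_down=-0.3,
        seed=seed,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path, config: SimulationConfig | None = None) -> Path:
    """Persist a dataset as MTX + TSVs plus a JSON run manifest."""
    outdir = Path(outdir)
    write_mtx_dir(dataset.counts, outdir, meta=dataset.meta)
    dataset.truth.nuclei.to_csv(outdir / "truth_nuclei.tsv", sep="\t", index=False)
    dataset.truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    if config is not None:
        manifest = {"config": config.to_dict(), "seed": config.seed}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return outdir
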