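"""Synthetic two-group cohort generation from a ground-truth Hopf model.

Every downstream stage (LEiDA, model fitting, EC optimization,
perturbation, statistics) is exercised on cohorts produced here, so the
generator emulates the derived structure of a resting-state fMRI study:
regional BOLD-like series (default 116 regions x 295 volumes at TR = 2 s,
band-limited 0.01-0.08 Hz), a symmetric structural connectome, region
metadata with left/right homolog pairs and functional-network labels, and
subject covariates (age, sex, education, mean framewise displacement) plus
substance-use severity indices with a planted monotone association to
global phase synchrony.

Two groups share the connectome but differ in coupling (group B gets a
higher global coupling and slightly raised bifurcation parameters in one
network by default), which shifts the occupancy of the metastable states
and gives the statistical layer a recoverable group effect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .hopf import (
    DEFAULT_A,
    DEFAULT_SIGMA,
    HopfModelSpec,
    SimulationConfig,
    normalize_coupling,
    simulate_hopf,
)
from .leida import bandpass_filter, hilbert_phase

__all__ = [
    "NETWORKS",
    "RegionalTimeSeriesSet",
    "CohortSpec",
    "generate_region_table",
    "generate_connectome",
    "generate_cohort",
    "default_cohort_spec",
    "write_cohort",
    "read_cohort",
]

NETWORKS = ("VIS", "SMN", "DAN", "VAN", "LIM", "FPN", "DMN", "SUB")

SEVERITY_INDICES = ("alcohol_use_30d", "intoxication_30d", "cocaine_use_30d")


@dataclass
class RegionalTimeSeriesSet:
    """Per-subject regions x volumes matrices sharing one sampling interval."""

    series: list
    tr: float
    subject_ids: list = field(default_factory=list)

    def __post_init__(self):
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i:03d}" for i in range(len(self.series))]

    def __len__(self):
        return len(self.series)

    def __iter__(self):
        return iter(self.series)

    @property
    def n_regions(self) -> int:
        return self.series[0].shape[0]

    def subset(self, idx) -> "RegionalTimeSeriesSet":
        return RegionalTimeSeriesSet(
            [self.series[i] for i in idx], self.tr, [self.subject_ids[i] for i in idx]
        )


def generate_region_table(n_regions: int, seed: int = 0) -> pd.DataFrame:
    """Region metadata with contralateral homolog pairs.

    Consecutive regions (2k, 2k+1) form a left/right pair sharing a network
    label; networks cycle through the eight categories so all are
    represented for n_regions >= 16.  The homolog relation is symmetric and
    irreflexive by construction.
    """
    if n_regions < 2 or n_regions % 2 != 0:
        raise ValueError("n_regions must be an even integer >= 2 for homolog pairing")
    rng = np.random.default_rng(seed)
    n_pairs = n_regions // 2
    # shuffle which network each pair belongs to, but keep all represented
    pair_networks = [NETWORKS[i % len(NETWORKS)] for i in range(n_pairs)]
    rng.shuffle(pair_networks)
    rows = []
    for p in range(n_pairs):
        net = pair_networks[p]
        left, right = 2 * p, 2 * p + 1
        rows.append((left, f"{net}_{p:02d}_L", "left", net, right))
        rows.append((right, f"{net}_{p:02d}_R", "right", net, left))
    return pd.DataFrame(
        rows, columns=["region_id", "name", "hemisphere", "network", "homolog_id"]
    )


def homolog_pairs(region_table: pd.DataFrame) -> list[tuple[int, int]]:
    """Unique (left, right) homolog index pairs from a region table."""
    pairs = []
    for rid, hid in zip(region_table["region_id"], region_table["homolog_id"]):
        if hid is not None and not (isinstance(hid, float) and np.isnan(hid)):
            a, b = int(rid), int(hid)
            if a < b:
                pairs.append((a, b))
    return pairs


def generate_connectome(region_table: pd.DataFrame, density: float = 0.35,
                        seed: int = 0) -> np.ndarray:
    """Synthetic structural connectome: exponential distance decay on a ring
    embedding, lognormal weight jitter, random sparsification to ``density``.

    Symmetric, non-negative, zero diagonal; homologous entries are always
    kept nonzero (they are exempt from sparsification, mirroring their
    special handling downstream).
    """
    if not (0.0 < density <= 1.0):
        raise ValueError("density must lie in (0, 1]")
    n = len(region_table)
    rng = np.random.default_rng(seed)
    # ring positions: pairs sit at mirrored angles so homologs are close
    pair = np.asarray(region_table["region_id"]) // 2
    angle = 2 * np.pi * pair / (n / 2) + np.where(
        np.asarray(region_table["hemisphere"]) == "right", 0.15, -0.15
    )
    d = np.abs(angle[:, None] - angle[None, :])
    d = np.minimum(d, 2 * np.pi - d)
    w = np.exp(-d / 0.5) * rng.lognormal(0.0, 0.4, size=(n, n))
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    if density < 1.0:
        iu = np.triu_indices(n, 1)
        keep = rng.random(iu[0].size) < density
        mask = np.ones((n, n), dtype=bool)
        mask[iu[0][~keep], iu[1][~keep]] = False
        mask[iu[1][~keep], iu[0][~keep]] = False
        w = np.where(mask, w, 0.0)
    for a, b in homolog_pairs(region_table):
        if w[a, b] == 0.0:
            w[a, b] = w[b, a] = np.exp(-0.3)  # restore the homolog edge
    return w


@dataclass
class CohortSpec:
    """Geometry and ground truth of a two-group synthetic cohort."""

    n_group_a: int = 45
    n_group_b: int = 43
    n_regions: int = 116
    n_volumes: int = 295
    tr: float = 2.0
    seed: int = 0
    ground_truth_a: HopfModelSpec | None = None
    ground_truth_b: HopfModelSpec | None = None
    burn_in: float = 200.0
    dt: float = 0.1
    severity_rho: float = 0.4

    def __post_init__(self):
        if self.n_volumes < 2:
            raise ValueError("n_volumes must be >= 2")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.ground_truth_a is not None and self.ground_truth_b is not None:
            if self.ground_truth_a.n_regions != self.ground_truth_b.n_regions:
                raise ValueError("ground truths must share n_regions")


def default_ground_truths(region_table: pd.DataFrame, sc: np.ndarray,
                          seed: int = 0, g_a: float = 0.16, g_b: float = 0.24,
                          sigma: float = 0.01, base_a: float = 0.05,
                          freq_range: tuple = (0.040, 0.052),
                          shifted_network: str = "DMN",
                          a_shift: float = 0.06):
    """Group ground truths: same connectome; group B gets a higher global
    coupling and raised bifurcation parameters in one network, which shifts
    the occupancy of the corresponding state.

    All regions sit just past the oscillatory onset (``a = base_a > 0``)
    with intrinsic frequencies following a smooth gradient along the ring
    embedding (default 0.040-0.052 Hz plus small jitter).  The coupling is
    degree-normalized (C / sqrt(d_i d_j)) before the usual max-0.2 rescale,
    which stabilizes the effective coupling across connectome realizations.
    As the global coupling grows, progressively longer arcs of the
    frequency gradient phase-lock, so the phase-locking patterns that the
    eigenvector states capture - and hence the state occupancies - change
    over the whole sweep range and identify the coupling.  A near-critical
    noise regime (a < 0 everywhere) produces state statistics that barely
    depend on G at this network size and is not used as the default.
    """
    n = len(region_table)
    n_pairs = n // 2
    rng = np.random.default_rng(seed)
    pair = np.asarray(region_table["region_id"]) // 2
    f0, f1 = freq_range
    freqs = f0 + (f1 - f0) * pair / max(n_pairs - 1, 1) + rng.normal(0, 0.0003, n)
    omega = 2 * np.pi * np.clip(freqs, 0.015, 0.075)
    degree = sc.sum(axis=1)
    if np.any(degree <= 0):
        raise ValueError("connectome has an isolated region")
    coupling = normalize_coupling(sc / np.sqrt(np.outer(degree, degree)))
    a_base = np.full(n, base_a)
    spec_a = HopfModelSpec(a=a_base, omega=omega, coupling=coupling, g=g_a, sigma=sigma)
    a_b = a_base.copy()
    a_b[np.asarray(region_table["network"]) == shifted_network] += a_shift
    spec_b = HopfModelSpec(a=a_b, omega=omega, coupling=coupling, g=g_b, sigma=sigma)
    return spec_a, spec_b


def default_cohort_spec(n_group_a: int = 45, n_group_b: int = 43,
                        n_regions: int = 116, n_volumes: int = 295,
                        tr: float = 2.0, seed: int = 0, **gt_kwargs) -> tuple:
    """Convenience constructor: region table, connectome, ground truths and
    the assembled CohortSpec with study-default geometry."""
    region_table = generate_region_table(n_regions, seed=seed)
    sc = generate_connectome(region_table, density=0.6, seed=seed + 1)
    gt_a, gt_b = default_ground_truths(region_table, sc, seed=seed + 2, **gt_kwargs)
    spec = CohortSpec(
        n_group_a=n_group_a, n_group_b=n_group_b, n_regions=n_regions,
        n_volumes=n_volumes, tr=tr, seed=seed,
        ground_truth_a=gt_a, ground_truth_b=gt_b,
    )
    return spec, region_table, sc


def _mean_order_parameter(series: np.ndarray, tr: float) -> float:
    """Time-averaged Kuramoto order parameter of a regional series: a scalar
    measure of global phase synchrony, monotone in the occupancy of the
    globally synchronized state."""
    theta = hilbert_phase(bandpass_filter(series, tr))
    return float(np.abs(np.exp(1j * theta).mean(axis=0)).mean())


def _planted_severity(sync: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Noisy monotone function of a synchrony score with Spearman target ~rho."""
    from scipy.stats import rankdata

    z = (rankdata(sync) - 0.5) / sync.size
    noise = rng.standard_normal(sync.size)
    latent = rho * (z - z.mean()) / z.std() + np.sqrt(max(1 - rho**2, 0.0)) * noise
    return np.round(np.clip(latent * 6 + 12, 0, 30), 1)  # days-of-use-like scale


def generate_cohort(spec: CohortSpec, region_table: pd.DataFrame | None = None):
    """Simulate a two-group cohort from the ground-truth models.

    Returns ``(cohort, meta, ground_truth)`` where ``cohort`` is a
    RegionalTimeSeriesSet (group A subjects first), ``meta`` a covariate
    table with one row per subject and no missing values, and
    ``ground_truth`` a record of the generating models.

    Each subject is an independent noise realization of their group's model.
    Covariates: age ~ U(18,50), sex ~ Bernoulli(0.84), education ~ U(6,20),
    mean FD ~ half-normal.  Severity indices (group B only in analyses, but
    generated for all) are rank-noisy functions of each subject's mean
    phase-synchrony with target Spearman rho ``spec.severity_rho``.
    """
    if spec.ground_truth_a is None or spec.ground_truth_b is None:
        raise ValueError("CohortSpec must carry both ground-truth models")
    min_vol = 16  # band-pass filter padding requirement
    if spec.n_volumes <= min_vol:
        raise ValueError(f"n_volumes must exceed the filter warm-up ({min_vol})")
    rng = np.random.default_rng(spec.seed)
    duration = spec.n_volumes * spec.tr
    series, groups = [], []
    for g_label, gt, n_sub in (("A", spec.ground_truth_a, spec.n_group_a),
                               ("B", spec.ground_truth_b, spec.n_group_b)):
        for _ in range(n_sub):
            sub_seed = int(rng.integers(2**31 - 1))
            config = SimulationConfig(duration=duration, tr=spec.tr, dt=spec.dt,
                                      burn_in=spec.burn_in, seed=sub_seed)
            series.append(simulate_hopf(gt, config).sampled_x)
            groups.append(g_label)
    n_total = len(series)
    cohort = RegionalTimeSeriesSet(series, spec.tr)

    sync = np.array([_mean_order_parameter(s, spec.tr) for s in series])
    meta = pd.DataFrame({
        "subject_id": cohort.subject_ids,
        "group": groups,
        "age": np.round(rng.uniform(18, 50, n_total), 1),
        "sex": (rng.random(n_total) < 0.84).astype(int),
        "education": np.round(rng.uniform(6, 20, n_total), 1),
        "mean_fd": np.round(np.abs(rng.normal(0.0, 0.1, n_total)) + 0.02, 4),
    })
    for idx_name in SEVERITY_INDICES:
        meta[idx_name] = _planted_severity(sync, spec.severity_rho, rng)
    assert not meta.isna().any().any()

    ground_truth = {
        "g_a": spec.ground_truth_a.g,
        "g_b": spec.ground_truth_b.g,
        "sigma": spec.ground_truth_a.sigma,
        "a_a": spec.ground_truth_a.a.tolist(),
        "a_b": spec.ground_truth_b.a.tolist(),
        "omega": spec.ground_truth_a.omega.tolist(),
        "seed": spec.seed,
    }
    return cohort, meta, ground_truth


# ---------------------------------------------------------------------------
# on-disk layout: manifest + one delimited matrix per subject
# ---------------------------------------------------------------------------

def write_cohort(out_dir, cohort: RegionalTimeSeriesSet, meta: pd.DataFrame,
                 region_table: pd.DataFrame, sc: np.ndarray,
                 ground_truth: dict | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, series in zip(cohort.subject_ids, cohort.series):
        np.savetxt(out / f"{sid}.tsv", series, delimiter="\t", fmt="%.6g")
    meta.to_csv(out / "covariates.tsv", sep="\t", index=False)
    region_table.to_csv(out / "regions.tsv", sep="\t", index=False)
    np.savetxt(out / "sc.tsv", sc, delimiter="\t", fmt="%.6g")
    manifest = {"tr": cohort.tr, "subjects": list(cohort.subject_ids),
                "n_regions": cohort.n_regions}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    if ground_truth is not None:
        (out / "ground_truth.json").write_text(json.dumps(ground_truth, indent=1))


def read_cohort(in_dir):
    """Inverse of :func:`write_cohort`; returns (cohort, meta, region_table, sc)."""
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    series = [np.loadtxt(src / f"{sid}.tsv", delimiter="\t", ndmin=2)
              for sid in manifest["subjects"]]
    cohort = RegionalTimeSeriesSet(series, manifest["tr"], manifest["subjects"])
    meta = pd.read_csv(src / "covariates.tsv", sep="\t")
    region_table = pd.read_csv(src / "regions.tsv", sep="\t")
    sc = np.loadtxt(src / "sc.tsv", delimiter="\t", ndmin=2)
    return cohort, meta, region_table, sc
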