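"""Synthetic cohorts and stained-tile pairs for marginal zone lymphoma analyses.

Two generators live here:

* :func:`generate_cohort` draws a patient cohort whose structure mirrors a
  retrospective MZL series: binary clinical covariates, an integer MZL-IPI
  score, beta-distributed marker positivity percentages with a latent Gaussian
  copula correlation structure, exponential proportional-hazards survival for
  OS and PFS with administrative plus random censoring, and a logistic
  histologic-transformation model driven by one marker.

* :func:`generate_tile_pair` synthesises a registered (or deliberately
  shifted) pair of H&E / single-marker IHC RGB tiles through a Beer-Lambert
  forward model, with full ground truth (cell centres, radii, positive labels,
  shift) so the quantification pipeline can be validated in closed loop.

Both are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CohortSpec",
    "PatientRecord",
    "TileSpec",
    "StainTilePair",
    "generate_cohort",
    "generate_tile_pair",
    "write_cohort_csv",
    "read_cohort_csv",
    "HEMATOXYLIN_OD",
    "DAB_OD",
]

# Standard optical-density unit vectors for hematoxylin counterstain and DAB
# chromogen (Ruifrok & Johnston convention), L2-normalised.
HEMATOXYLIN_OD = np.array([0.650, 0.704, 0.286])
HEMATOXYLIN_OD = HEMATOXYLIN_OD / np.linalg.norm(HEMATOXYLIN_OD)
DAB_OD = np.array([0.269, 0.568, 0.778])
DAB_OD = DAB_OD / np.linalg.norm(DAB_OD)

#: Prevalences of the binary clinical covariates, as observed proportions in
#: a 146-patient MZL series (male sex, age >= 60, gastric involvement, B
#: symptoms, comorbidities and treatment exposure).
DEFAULT_COVARIATE_PROBS: dict[str, float] = {
    "sex_male": 83 / 146,
    "age_ge_60": 48 / 146,
    "b_symptoms": 0.2466,
    "hypertension": 0.1781,
    "diabetes": 0.0822,
    "gastric_site": 41 / 146,
    "chemo": 127 / 146,
    "rituximab": 0.8082,
    "radiotherapy": 0.1507,
    "surgery": 0.3014,
}

#: Histologic subtype frequencies (MALT / SMZL / NMZL / NOS) in the same series.
DEFAULT_SUBTYPE_PROBS: dict[str, float] = {
    "MALT": 119 / 146,
    "SMZL": 19 / 146,
    "NMZL": 7 / 146,
    "NOS": 1 / 146,
}

#: Default integer MZL-IPI distribution over scores 0..5, chosen so that
#: P(score > 2) ~ 0.34, the fraction of high-score patients in the series.
DEFAULT_IPI_PROBS = (0.20, 0.25, 0.21, 0.19, 0.10, 0.05)

#: Default marker panel: (mean positivity fraction, beta concentration).
#: B-cell markers (CD20) sit high, T-cell and proliferation markers lower.
DEFAULT_MARKER_PARAMS: dict[str, tuple[float, float]] = {
    "CD3": (0.30, 6.0),
    "CD21": (0.45, 5.0),
    "CD20": (0.80, 8.0),
    "BCL2": (0.60, 6.0),
    "KI67": (0.25, 6.0),
}


def _default_marker_corr(markers: Sequence[str]) -> np.ndarray:
    """Latent correlation with a few positive/negative blocks (CD3-CD20 and
    BCL2-CD3 positive, BCL2-KI67 negative), zero elsewhere."""
    idx = {m: i for i, m in enumerate(markers)}
    corr = np.eye(len(markers))

    def put(a: str, b: str, rho: float) -> None:
        if a in idx and b in idx:
            corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho

    put("CD3", "CD20", 0.30)
    put("BCL2", "CD3", 0.30)
    put("BCL2", "KI67", -0.30)
    return corr


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    Log hazard ratios are applied per covariate *unit*: binary covariates and
    the integer MZL-IPI enter as-is, marker columns enter as fractions in
    [0, 1] (percentage / 100). ``threshold_effects_os`` / ``_pfs`` plant a
    hazard step: ``{marker: (cutoff_pct, log_hr_above)}`` multiplies the
    hazard by ``exp(log_hr_above)`` for patients with marker > cutoff.

    Default event intensities reproduce the event profile of the reference
    series over a ~100-month horizon: overall mortality near 12% and a
    progression rate near 30%.
    """

    n_patients: int = 146
    marker_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_PARAMS)
    )
    marker_corr: np.ndarray | None = None
    ipi_probs: Sequence[float] = DEFAULT_IPI_PROBS
    covariate_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PROBS)
    )
    subtype_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_PROBS)
    )
    log_hr_os: Mapping[str, float] = field(default_factory=dict)
    log_hr_pfs: Mapping[str, float] = field(default_factory=dict)
    threshold_effects_os: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    threshold_effects_pfs: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    baseline_hazard: float = 0.0025  # death rate per month
    baseline_hazard_progression: float = 0.006  # progression-only rate per month
    censor_rate: float = 0.018  # per month
    admin_horizon: float = 100.0  # months
    transform_marker: str = "CD3"
    transform_intercept: float = -1.0
    transform_coef: float = -2.8  # log-odds for marker above the cutoff
    transform_cutoff_pct: float = 25.60
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be a positive integer")
        for name, (mean, conc) in self.marker_params.items():
            if not 0.0 < mean < 1.0:
                raise ValueError(f"marker {name!r}: beta mean must lie strictly in (0,1)")
            if conc <= 0:
                raise ValueError(f"marker {name!r}: beta concentration must be > 0")
        probs = np.asarray(self.ipi_probs, dtype=float)
        if probs.ndim != 1 or abs(probs.sum() - 1.0) > 1e-12 or (probs < 0).any():
            raise ValueError("ipi_probs must be a probability vector summing to 1")
        corr = self.resolved_corr()
        if corr.shape != (len(self.marker_params),) * 2:
            raise ValueError("marker_corr shape must match the number of markers")
        if not np.allclose(corr, corr.T):
            raise ValueError("marker_corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("marker_corr must have a unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-8:
            raise ValueError("marker_corr is not positive semi-definite")

    def resolved_corr(self) -> np.ndarray:
        if self.marker_corr is None:
            return _default_marker_corr(list(self.marker_params))
        return np.asarray(self.marker_corr, dtype=float)


@dataclass
class PatientRecord:
    """One synthetic patient; mirrors a row of the cohort table."""

    patient_id: str
    sex_male: int
    age_ge_60: int
    b_symptoms: int
    hypertension: int
    diabetes: int
    gastric_site: int
    subtype: str
    chemo: int
    rituximab: int
    radiotherapy: int
    surgery: int
    mzl_ipi: int
    markers: dict[str, float]
    os_months: float
    pfs_months: float
    os_event: int
    pfs_event: int
    transformed: int


def _linear_predictor(
    df: pd.DataFrame,
    markers: Sequence[str],
    coefs: Mapping[str, float],
    steps: Mapping[str, tuple[float, float]],
) -> np.ndarray:
    lp = np.zeros(len(df))
    for name, beta in coefs.items():
        if name in markers:
            lp += beta * df[name].to_numpy() / 100.0
        elif name in df.columns:
            lp += beta * df[name].to_numpy(dtype=float)
        else:
            raise KeyError(f"log-HR refers to unknown covariate {name!r}")
    for name, (cutoff_pct, beta) in steps.items():
        lp += beta * (df[name].to_numpy() > cutoff_pct)
    return lp


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Draw a synthetic cohort.

    Returns ``(cohort, ledger)``: the cohort as a DataFrame (one row per
    patient, marker positivity in percent 0-100, OS/PFS in months) and a
    ground-truth ledger recording every planted parameter. ``pfs_months <=
    os_months`` holds by construction because the PFS event time is the
    minimum of a latent progression time and the death time, both censored by
    the same censoring time.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    markers = list(spec.marker_params)

    cols: dict[str, object] = {"patient_id": [f"P{i:04d}" for i in range(n)]}
    for name, p in spec.covariate_probs.items():
        cols[name] = (rng.random(n) < p).astype(int)
    subtype_names = list(spec.subtype_probs)
    subtype_p = np.asarray(list(spec.subtype_probs.values()), dtype=float)
    subtype_p = subtype_p / subtype_p.sum()
    cols["subtype"] = rng.choice(subtype_names, size=n, p=subtype_p)
    ipi_probs = np.asarray(spec.ipi_probs, dtype=float)
    cols["mzl_ipi"] = rng.choice(len(ipi_probs), size=n, p=ipi_probs).astype(int)

    # Gaussian copula -> beta marginals for the marker positivity fractions.
    corr = spec.resolved_corr()
    latent = rng.multivariate_normal(np.zeros(len(markers)), corr, size=n, method="eigh")
    u = sps.norm.cdf(latent)
    for j, name in enumerate(markers):
        mean, conc = spec.marker_params[name]
        a, b = mean * conc, (1.0 - mean) * conc
        cols[name] = 100.0 * sps.beta.ppf(u[:, j], a, b)

    df = pd.DataFrame(cols)

    lp_os = _linear_predictor(df, markers, spec.log_hr_os, spec.threshold_effects_os)
    lp_pfs = _linear_predictor(df, markers, spec.log_hr_pfs, spec.threshold_effects_pfs)
    haz_death = spec.baseline_hazard * np.exp(lp_os)
    haz_prog = spec.baseline_hazard_progression * np.exp(lp_pfs)

    t_death = rng.exponential(1.0 / haz_death)
    t_prog = rng.exponential(1.0 / np.where(haz_prog > 0, haz_prog, np.inf))
    if spec.censor_rate > 0:
        t_cens = rng.exponential(1.0 / spec.censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, spec.admin_horizon)

    t_pfs_event = np.minimum(t_prog, t_death)
    df["os_months"] = np.minimum(t_death, t_cens)
    df["os_event"] = (t_death <= t_cens).astype(int)
    df["pfs_months"] = np.minimum(t_pfs_event, t_cens)
    df["pfs_event"] = (t_pfs_event <= t_cens).astype(int)

    # Logistic transformation model on the dichotomised driver marker.
    high = (df[spec.transform_marker].to_numpy() > spec.transform_cutoff_pct).astype(float)
    p_trans = 1.0 / (1.0 + np.exp(-(spec.transform_intercept + spec.transform_coef * high)))
    df["transformed"] = (rng.random(n) < p_trans).astype(int)

    df.attrs["markers"] = markers
    ledger = {
        "spec": _spec_to_jsonable(spec),
        "markers": markers,
        "true_log_hr_os": dict(spec.log_hr_os),
        "true_log_hr_pfs": dict(spec.log_hr_pfs),
        "true_threshold_effects_os": {k: list(v) for k, v in spec.threshold_effects_os.items()},
        "true_threshold_effects_pfs": {k: list(v) for k, v in spec.threshold_effects_pfs.items()},
        "true_transform": {
            "marker": spec.transform_marker,
            "intercept": spec.transform_intercept,
            "coef": spec.transform_coef,
            "cutoff_pct": spec.transform_cutoff_pct,
        },
    }
    return df, ledger


def _spec_to_jsonable(spec: CohortSpec) -> dict:
    out = asdict(spec)
    out["marker_corr"] = spec.resolved_corr().tolist()
    out["marker_params"] = {k: list(v) for k, v in spec.marker_params.items()}
    out["ipi_probs"] = list(spec.ipi_probs)
    out["threshold_effects_os"] = {k: list(v) for k, v in spec.threshold_effects_os.items()}
    out["threshold_effects_pfs"] = {k: list(v) for k, v in spec.threshold_effects_pfs.items()}
    return out


def cohort_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    """View the cohort table as a list of :class:`PatientRecord`."""
    markers = df.attrs.get("markers", [])
    recs = []
    for _, row in df.iterrows():
        recs.append(
            PatientRecord(
                patient_id=row["patient_id"],
                sex_male=int(row["sex_male"]),
                age_ge_60=int(row["age_ge_60"]),
                b_symptoms=int(row["b_symptoms"]),
                hypertension=int(row["hypertension"]),
                diabetes=int(row["diabetes"]),
                gastric_site=int(row["gastric_site"]),
                subtype=row["subtype"],
                chemo=int(row["chemo"]),
                rituximab=int(row["rituximab"]),
                radiotherapy=int(row["radiotherapy"]),
                surgery=int(row["surgery"]),
                mzl_ipi=int(row["mzl_ipi"]),
                markers={m: float(row[m]) for m in markers},
                os_months=float(row["os_months"]),
                pfs_months=float(row["pfs_months"]),
                os_event=int(row["os_event"]),
                pfs_event=int(row["pfs_event"]),
                transformed=int(row["transformed"]),
            )
        )
    return recs


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_cohort_csv(path, markers: Sequence[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if markers is None:
        known = set(DEFAULT_MARKER_PARAMS)
        markers = [c for c in df.columns if c in known]
    df.attrs["markers"] = list(markers)
    return df


# ---------------------------------------------------------------------------
# Stained-tile pairs
# ---------------------------------------------------------------------------


@dataclass
class TileSpec:
    """Parameters of the stained-tile generator.

    ``shift`` is the (rows, cols) integer translation applied to the IHC tile
    relative to the H&E tile; vacated pixels are filled with white (zero
    optical density, i.e. blank glass). ``noise_sd`` is Gaussian pixel noise
    on the 0-255 intensity scale.
    """

    width: int = 256
    height: int = 256
    n_cells: int = 150
    cell_radius_px: tuple[int, int] = (4, 7)
    positive_fraction: float = 0.4
    stain_vectors: tuple[np.ndarray, np.ndarray] = (HEMATOXYLIN_OD, DAB_OD)
    noise_sd: float = 2.0
    shift: tuple[int, int] = (0, 0)
    nuclear_od: float = 0.9
    chromogen_od: float = 1.0
    pixel_size: float = 0.5  # microns / px, metadata only
    seed: int = 0
    max_placement_tries: int = 200

    def validate(self) -> None:
        v0, v1 = (np.asarray(v, dtype=float) for v in self.stain_vectors)
        for v in (v0, v1):
            if (v < 0).any():
                raise ValueError("stain vectors must be non-negative")
            if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                raise ValueError("stain vectors must be unit L2 norm")
        if np.linalg.matrix_rank(np.stack([v0, v1])) < 2:
            raise ValueError("stain vectors must be linearly independent")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must be in [0, 1]")
        lo, hi = self.cell_radius_px
        if lo < 1 or hi < lo:
            raise ValueError("cell_radius_px must be a valid (low, high) range")


@dataclass
class StainTilePair:
    """A paired H&E / IHC tile with optional generator ground truth."""

    he_rgb: np.ndarray
    ihc_rgb: np.ndarray
    pixel_size: float = 0.5
    ground_truth: dict | None = None


def _place_cells(spec: TileSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping cell centres; raises when packing fails."""
    lo, hi = spec.cell_radius_px
    centers = np.empty((spec.n_cells, 2))
    radii = np.empty(spec.n_cells)
    placed = 0
    tries = 0
    budget = spec.max_placement_tries * max(spec.n_cells, 1)
    while placed < spec.n_cells:
        if tries >= budget:
            density = spec.n_cells * np.pi * ((lo + hi) / 2) ** 2 / (spec.width * spec.height)
            raise RuntimeError(
                f"could not place {spec.n_cells} non-overlapping cells "
                f"(approximate packing density {density:.2f}); reduce n_cells or radius"
            )
        tries += 1
        r = rng.uniform(lo, hi)
        c = np.array(
            [rng.uniform(r + 1, spec.height - r - 1), rng.uniform(r + 1, spec.width - r - 1)]
        )
        if placed:
            d = np.hypot(*(centers[:placed] - c).T)
            if (d < radii[:placed] + r + 1).any():
                continue
        centers[placed] = c
        radii[placed] = r
        placed += 1
    return centers, radii


def _disk_mask(shape: tuple[int, int], centers: np.ndarray, radii: np.ndarray) -> np.ndarray:
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    mask = np.zeros(shape, dtype=bool)
    for (cy, cx), r in zip(centers, radii):
        sel = (rows - cy) ** 2 + (cols - cx) ** 2 <= r**2
        mask |= sel
    return mask


def _render(od_maps: list[np.ndarray], vectors: list[np.ndarray], noise_sd: float,
            rng: np.random.Generator) -> np.ndarray:
    """Beer-Lambert forward model: intensity = 255 * exp(-sum OD_s * vec_s)."""
    h, w = od_maps[0].shape
    od = np.zeros((h, w, 3))
    for amt, vec in zip(od_maps, vectors):
        od += amt[:, :, None] * np.asarray(vec)[None, None, :]
    img = 255.0 * np.exp(-od)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _translate(img: np.ndarray, shift: tuple[int, int], fill: int = 255) -> np.ndarray:
    dy, dx = shift
    out = np.full_like(img, fill)
    h, w = img.shape[:2]
    ys = slice(max(dy, 0), h + min(dy, 0))
    xs = slice(max(dx, 0), w + min(dx, 0))
    ys_src = slice(max(-dy, 0), h + min(-dy, 0))
    xs_src = slice(max(-dx, 0), w + min(-dx, 0))
    out[ys, xs] = img[ys_src, xs_src]
    return out


def generate_tile_pair(spec: TileSpec) -> StainTilePair:
    """Synthesise a paired H&E / IHC tile with known ground truth.

    All cells carry nuclear counterstain on both tiles; exactly
    ``round(n_cells * positive_fraction)`` cells additionally carry chromogen
    on the IHC tile. The IHC tile is then translated by ``spec.shift``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    centers, radii = _place_cells(spec, rng)

    n_pos = int(round(spec.n_cells * spec.positive_fraction))
    order = rng.permutation(spec.n_cells)
    positive = np.zeros(spec.n_cells, dtype=bool)
    positive[order[:n_pos]] = True

    shape = (spec.height, spec.width)
    nuc_all = _disk_mask(shape, centers, radii).astype(float) * spec.nuclear_od
    pos_mask = _disk_mask(shape, centers[positive], radii[positive]).astype(float)
    chrom = pos_mask * spec.chromogen_od

    nuc_vec, chrom_vec = spec.stain_vectors
    he = _render([nuc_all], [nuc_vec], spec.noise_sd, rng)
    ihc = _render([nuc_all, chrom], [nuc_vec, chrom_vec], spec.noise_sd, rng)
    ihc = _translate(ihc, spec.shift, fill=255)

    gt = {
        "centers": centers.tolist(),
        "radii": radii.tolist(),
        "positive": positive.astype(int).tolist(),
        "n_positive": int(n_pos),
        "positive_fraction": spec.positive_fraction,
        "shift": list(spec.shift),
        "stain_vectors": [np.asarray(v).tolist() for v in spec.stain_vectors],
    }
    return StainTilePair(he_rgb=he, ihc_rgb=ihc, pixel_size=spec.pixel_size, ground_truth=gt)


def write_ground_truth(pair: StainTilePair, path) -> None:
    with open(path, "w") as fh:
        json.dump(pair.ground_truth, fh, indent=1, sort_keys=True)
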