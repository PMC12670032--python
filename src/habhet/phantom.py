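"""Synthetic multi-sequence phantom cohorts with controllable ITH/PTH.

Each case is an ellipsoidal "tumor" embedded in a background volume, imaged
in four channels that are distinct affine mixes of two shared Gaussian
random field (GRF) textures plus channel noise. The class label (emulating
e.g. microvascular-invasion status) is coupled to the texture variance
inside the tumor and — more strongly — in the peritumoral shell, so
high-class cases carry more intra- and peri-tumoral heterogeneity. Two
observer mask variants are produced by perturbing the ellipsoid's implicit
surface with a smooth random field. Survival times follow a Weibull model
whose hazard is multiplied by exp(log HR) for the high class, with uniform
administrative censoring.

The generator writes the same NIfTI + YAML manifest layout the IO module
consumes, or returns cases in memory for fast simulation studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io import SEQUENCES, VolumeStack, save_case, write_manifest


@dataclass
class PhantomSpec:
    """Study conditions for a synthetic cohort.

    Defaults: 64 x 64 x 24 voxels at 1 x 1 x 3 mm; tumor radius 7-12 mm;
    GRF correlation length 4 mm; high/low texture-variance ratio 4 with the
    class effect 1.5x stronger peritumorally; label prevalence 0.25; Weibull
    survival with class log-HR ln(2.2); observer jitter amplitude 1 mm.
    """

    n_cases: int = 40
    shape: tuple[int, int, int] = (64, 64, 24)
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    tumor_radius_mm: tuple[float, float] = (7.0, 12.0)
    corr_length_mm: float = 4.0
    sigma2_low: float = 0.5
    sigma2_ratio: float = 1.5          # sigma2_high / sigma2_low
    peri_effect: float = 1.5           # extra class effect in the peritumoral shell
    peri_shell_mm: float = 8.0
    # log-sd of the spatial modulation of texture amplitude. The class effect
    # lives mainly here: high-class lesions are patchy (quiet and wild
    # subregions), most strongly in the peritumoral shell, while the total
    # variance differs only modestly — so the signal sits in the *spatial
    # arrangement* that habitat-level dispersion captures, not in whole-ROI
    # summary statistics
    patchiness_low: float = 0.2
    patchiness_high: float = 0.7
    patchiness_peri_high: float = 1.1
    background_amp: float = 0.4        # parenchyma-like background texture level
    channel_noise_sd: float = 0.2
    background_sd_jitter: float = 0.35  # lognormal sd of per-case background noise level
    prevalence: float = 0.25
    weibull_shape: float = 1.3
    weibull_scale_rfs: float = 110.0   # months; baseline (low class)
    weibull_scale_os: float = 220.0
    log_hr: float = float(np.log(2.2))
    censor_range: tuple[float, float] = (60.0, 120.0)
    jitter_mm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if self.sigma2_low <= 0 or self.sigma2_ratio <= 0:
            raise ValueError("texture variances must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


#: per-channel (mix of texture 1, mix of texture 2, tumor contrast offset);
#: offsets are strong, as HCC lesions are conspicuous on all four sequences
_CHANNEL_MIX = {
    "T2": (1.0, 0.3, 2.0),
    "PRE": (0.5, -0.8, -1.5),
    "AP": (-0.7, 1.0, 2.5),
    "HBP": (0.9, 0.9, -2.0),
}


def _grf(rng: np.random.Generator, shape, spacing, corr_mm: float) -> np.ndarray:
    """Unit-variance Gaussian random field with isotropic physical correlation."""
    sig = [corr_mm / s for s in spacing]
    f = gaussian_filter(rng.standard_normal(shape), sig, mode="wrap")
    return f / f.std()


def _ellipsoid_field(shape, spacing, center_mm, radii_mm) -> np.ndarray:
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return (
        ((xx - center_mm[0]) / radii_mm[0]) ** 2
        + ((yy - center_mm[1]) / radii_mm[1]) ** 2
        + ((zz - center_mm[2]) / radii_mm[2]) ** 2
    )


def generate_case(
    spec: PhantomSpec,
    class_label: int,
    seed: int,
    case_id: str = "case",
) -> dict:
    """Generate one phantom case; deterministic per (spec, label, seed).

    Returns a dict with keys ``stack`` (raw VolumeStack), ``masks`` (two
    observer variants of the tumor mask), ``label``, and ``survival``.
    """
    rng = np.random.default_rng(seed)
    shape, spacing = spec.shape, spec.spacing
    extent = [n * s for n, s in zip(shape, spacing)]

    r_lo, r_hi = spec.tumor_radius_mm
    radii = rng.uniform(r_lo, r_hi, size=3)
    if any(2 * r >= e for r, e in zip(radii, extent)):
        raise ValueError("tumor larger than the volume")
    center = [e / 2 + rng.uniform(-2, 2) for e in extent]

    f = _ellipsoid_field(shape, spacing, center, radii)
    tumor = f <= 1.0
    if not tumor.any():
        raise ValueError("degenerate tumor: no voxels inside the ellipsoid")

    # observer variants: perturb the implicit surface with a smooth field
    masks = {}
    for obs in (1, 2):
        if spec.jitter_mm <= 0:
            masks[f"tumor_obs{obs}"] = tumor.copy()
        else:
            pert = _grf(rng, shape, spacing, 2 * spec.corr_length_mm)
            amp = spec.jitter_mm / float(np.mean(radii))  # ~mm on the boundary
            masks[f"tumor_obs{obs}"] = (f + amp * pert) <= 1.0
    if not masks["tumor_obs1"].any():
        masks["tumor_obs1"] = tumor.copy()
    if not masks["tumor_obs2"].any():
        masks["tumor_obs2"] = tumor.copy()

    # class-linked texture variance, stronger peritumorally for the high class
    s2_t = spec.sigma2_low * (spec.sigma2_ratio if class_label else 1.0)
    s2_p = spec.sigma2_low * (spec.sigma2_ratio * spec.peri_effect if class_label else 1.0)
    shell = (f > 1.0) & (_ellipsoid_field(
        shape, spacing, center, [r + spec.peri_shell_mm for r in radii]) <= 1.0)

    amp = np.full(shape, spec.background_amp)
    amp[shell] = np.sqrt(s2_p)
    amp[tumor] = np.sqrt(s2_t)
    # subregion-scale amplitude modulation (lognormal, mean-amplitude
    # preserving): the high class concentrates variance in patchy subregions,
    # most strongly peritumorally
    s_tum = spec.patchiness_high if class_label else spec.patchiness_low
    s_per = spec.patchiness_peri_high if class_label else spec.patchiness_low
    if s_tum > 0 or s_per > 0:
        mod = _grf(rng, shape, spacing, 2 * spec.corr_length_mm)
        amp[tumor] = amp[tumor] * np.exp(s_tum * mod[tumor] - s_tum**2 / 2)
        amp[shell] = amp[shell] * np.exp(s_per * mod[shell] - s_per**2 / 2)

    tex1 = _grf(rng, shape, spacing, spec.corr_length_mm)
    tex2 = _grf(rng, shape, spacing, spec.corr_length_mm)
    bg_sd = float(np.exp(rng.normal(0.0, spec.background_sd_jitter)))
    gain = float(np.exp(rng.normal(0.0, 0.2)))

    volumes = {}
    for seq in SEQUENCES:
        m1, m2, contrast = _CHANNEL_MIX[seq]
        vol = amp * (m1 * tex1 + m2 * tex2)
        vol += contrast * tumor
        vol += spec.channel_noise_sd * bg_sd * rng.standard_normal(shape)
        volumes[seq] = gain * vol
    stack = VolumeStack(case_id, volumes, spacing)

    # Weibull survival with class-proportional hazard and uniform censoring
    survival = {"case_id": case_id}
    for endpoint, scale in (("rfs", spec.weibull_scale_rfs), ("os", spec.weibull_scale_os)):
        u = rng.uniform()
        t_event = scale * (-np.log(u) / np.exp(spec.log_hr * class_label)) ** (
            1.0 / spec.weibull_shape)
        c = rng.uniform(*spec.censor_range)
        survival[f"time_{endpoint}"] = float(min(t_event, c))
        survival[f"event_{endpoint}"] = int(t_event <= c)

    return {"case_id": case_id, "stack": stack, "masks": masks,
            "label": int(class_label), "survival": survival}


def cohort_labels(spec: PhantomSpec) -> np.ndarray:
    """Prevalence-matched label vector, shuffled deterministically."""
    n_pos = int(round(spec.prevalence * spec.n_cases))
    labels = np.zeros(spec.n_cases, int)
    labels[:n_pos] = 1
    return np.random.default_rng(spec.seed).permutation(labels)


def generate_cohort(spec: PhantomSpec, out_dir: str | Path | None = None) -> dict:
    """Generate a full cohort; optionally write NIfTI files + manifest.

    Returns ``{"cases": [...], "table": CohortTable}`` where the table holds
    case_id, label and the survival columns. With ``out_dir`` set, every
    case is written to disk and a YAML manifest is produced.
    """
    labels = cohort_labels(spec)
    seeds = np.random.SeedSequence(spec.seed).generate_state(spec.n_cases) % (2**31)
    cases, rows, entries = [], [], []
    for i in range(spec.n_cases):
        cid = f"case{i:03d}"
        case = generate_case(spec, int(labels[i]), int(seeds[i]), cid)
        cases.append(case)
        rows.append({"case_id": cid, "label": int(labels[i]), **{
            k: v for k, v in case["survival"].items() if k != "case_id"}})
        if out_dir is not None:
            entry = save_case(case["stack"], case["masks"], Path(out_dir) / cid)
            entry["label"] = int(labels[i])
            entries.append(entry)
    table = pd.DataFrame(rows).set_index("case_id")
    if out_dir is not None:
        write_manifest(entries, Path(out_dir) / "manifest.yaml")
        table.to_csv(Path(out_dir) / "cohort.csv")
    return {"cases": cases, "table": table}
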