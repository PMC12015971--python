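"""Synthetic phantom-and-cohort generator.

Every downstream stage of the pipeline is exercised against cohorts drawn
here: for each simulated subject the generator produces (i) ground-truth
tissue parameters and clinical covariates and (ii) a dual-echo phantom of
a sciatic-nerve cross-section with a matching integer label map.

Subject truth
-------------
Fascicle pseudo-T2*, epineurium pseudo-T2*, whole-nerve cross-sectional
area (CSA) and the fascicular area fraction are drawn from per-group
normal distributions truncated symmetrically about their means (so the
configured group means are exact expectations). Clinical and
nerve-conduction covariates are tied to fascicle pT2* through a Gaussian
copula: a target Spearman correlation rho_s is converted to the latent
normal correlation r = 2 sin(pi * rho_s / 6) — exact for bivariate
normals — and each covariate is produced by pushing its latent normal
through the inverse CDF of its marginal.

Phantom geometry
----------------
Each slice holds one elliptical nerve cross-section rendered to the exact
voxel count implied by the subject's true CSA. The interior is divided
into fascicle territories around randomly packed seed points; voxels
nearest to territory boundaries or to the nerve edge are labelled inner
epineurium until the epineurium voxel budget — set by the true fascicular
fraction — is spent. This reproduces the appearance of hyperintense
fascicles separated and surrounded by hypointense epineurium, and makes
rendered areas and fractions match the truth to within a voxel.

Signal model
------------
Each compartment decays mono-exponentially: S(t) = A * exp(-t / T2*),
with the amplitude A absorbing proton density and T1/TR/flip-angle
weighting. Fat is assumed suppressed by the sequence's binomial
excitation and is not simulated; the background is muscle. Noise is
Rician by default (magnitude MRI), Gaussian on request, with sigma set by
the fascicle TE1 signal divided by the configured SNR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterator

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import (
    GROUP_ATTRV,
    GROUP_HC,
    KNOWN_GROUPS,
    LABEL_BACKGROUND,
    LABEL_EPINEURIUM,
    LABEL_FASCICLE,
    AcquisitionSpec,
    CompartmentSpec,
    CovariateModel,
    GeometryConfig,
    GroupDistributions,
    Marginal,
    NormalSpec,
    RunConfig,
    default_compartments,
    default_covariate_model,
    default_group_distributions,
)
from .morphometry import NerveLabelMap
from .relaxometry import EchoPairVolume

__all__ = [
    "SubjectTruth",
    "PackingError",
    "spearman_to_latent",
    "draw_subject",
    "build_phantom",
    "build_label_map",
    "render_echoes",
    "simulate_subject",
    "iter_cohort",
    "generate_cohort",
    "perturb_mask",
    "TRUTH_COLUMNS",
]

TRUTH_COLUMNS = [
    "subject_id",
    "group",
    "true_fascicle_t2star_ms",
    "true_epineurium_t2star_ms",
    "true_csa_mm2",
    "true_fasc_fraction",
    "age",
    "sex",
    "nis",
    "nis_ll",
    "pnd",
    "cmap_peroneal_mv",
    "cmap_tibial_mv",
    "snap_sural_uv",
    "ncv_peroneal_ms",
    "ncv_tibial_ms",
    "seed",
]


class PackingError(RuntimeError):
    """Fascicle seed packing failed within the bounded retry budget."""


@dataclass
class SubjectTruth:
    """Ground truth for one simulated subject."""

    subject_id: str
    group: str
    fascicle_t2star_ms: float
    epineurium_t2star_ms: float
    csa_mm2: float
    fascicular_fraction: float
    covariates: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group not in KNOWN_GROUPS:
            raise ValueError(f"unknown group {self.group!r}")

    def as_row(self) -> dict[str, Any]:
        row = {
            "subject_id": self.subject_id,
            "group": self.group,
            "true_fascicle_t2star_ms": self.fascicle_t2star_ms,
            "true_epineurium_t2star_ms": self.epineurium_t2star_ms,
            "true_csa_mm2": self.csa_mm2,
            "true_fasc_fraction": self.fascicular_fraction,
        }
        row.update(self.covariates)
        row["seed"] = self.seed
        return row


def spearman_to_latent(rho_s: float) -> float:
    """Latent normal correlation reproducing a target Spearman rho for a
    Gaussian copula: r = 2 sin(pi * rho_s / 6)."""
    if not -1.0 <= rho_s <= 1.0:
        raise ValueError(f"rank correlation outside [-1, 1]: {rho_s}")
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def _truncated_normal_ppf(u: float, spec: NormalSpec) -> float:
    """Inverse CDF of the symmetric truncation of N(mean, sd^2)."""
    if spec.sd == 0:
        return spec.mean
    half = spec.mean - spec.floor
    if spec.ceil is not None:
        half = min(half, spec.ceil - spec.mean)
    if half <= 0:
        # floor at/above the mean: fall back to one-sided truncation
        a = (spec.floor - spec.mean) / spec.sd
        return float(sps.truncnorm.ppf(u, a, np.inf, loc=spec.mean, scale=spec.sd))
    a = -half / spec.sd
    return float(sps.truncnorm.ppf(u, a, -a, loc=spec.mean, scale=spec.sd))


def _marginal_ppf(u: float, marg: Marginal) -> float:
    p = marg.params
    if marg.kind == "constant":
        return float(p["value"])
    if marg.kind == "normal":
        x = sps.norm.ppf(u, loc=p["mean"], scale=p["sd"])
        lo, hi = p.get("lo"), p.get("hi")
        if lo is not None:
            x = max(x, lo)
        if hi is not None:
            x = min(x, hi)
        return float(x)
    if marg.kind == "lognormal":
        x = math.exp(math.log(p["median"]) + p["sigma"] * sps.norm.ppf(u))
        hi = p.get("hi")
        if hi is not None:
            x = min(x, hi)
        return float(x)
    if marg.kind == "binary":
        return 1.0 if u > 1.0 - p["p"] else 0.0
    if marg.kind == "ordinal":
        cum = np.cumsum(p["probs"])
        idx = int(np.searchsorted(cum, u, side="left"))
        idx = min(idx, len(p["values"]) - 1)
        return float(p["values"][idx])
    raise ValueError(f"unknown marginal kind {marg.kind!r}")


def draw_subject(
    group: str,
    dists: dict[str, GroupDistributions] | GroupDistributions,
    covmodel: CovariateModel | None = None,
    rng: np.random.Generator | None = None,
    subject_id: str = "",
    seed: int = 0,
) -> SubjectTruth:
    """Draw one subject's ground truth for ``group``.

    Tissue parameters come from the group's truncated normals; covariates
    share a Gaussian copula with the fascicle pT2* latent variable, so
    the configured Spearman correlations with fascicle pT2* hold exactly
    for continuous marginals (discrete marginals — sex, PND — are
    attenuated by ties).
    """
    if rng is None:
        rng = np.random.default_rng()
    if isinstance(dists, GroupDistributions):
        gd = dists
    else:
        if group not in dists:
            raise ValueError(f"unknown group {group!r}; expected one of {sorted(dists)}")
        gd = dists[group]
    if group not in KNOWN_GROUPS:
        raise ValueError(f"unknown group {group!r}")
    covmodel = covmodel if covmodel is not None else default_covariate_model()

    z0 = rng.standard_normal()
    u0 = sps.norm.cdf(z0)
    fasc_t2 = _truncated_normal_ppf(u0, gd.fascicle_t2star)
    epi_t2 = _truncated_normal_ppf(sps.norm.cdf(rng.standard_normal()), gd.epineurium_t2star)
    csa = _truncated_normal_ppf(sps.norm.cdf(rng.standard_normal()), gd.csa_mm2)
    frac = _truncated_normal_ppf(sps.norm.cdf(rng.standard_normal()), gd.fascicular_fraction)

    covariates: dict[str, float] = {}
    for cov in covmodel.covariates:
        rho = cov.rho_s.get(group, 0.0)
        r = spearman_to_latent(rho)
        z = r * z0 + math.sqrt(1.0 - r * r) * rng.standard_normal()
        marg = cov.marginals[group]
        covariates[cov.name] = _marginal_ppf(sps.norm.cdf(z), marg)

    return SubjectTruth(
        subject_id=subject_id or f"{group}-000",
        group=group,
        fascicle_t2star_ms=fasc_t2,
        epineurium_t2star_ms=epi_t2,
        csa_mm2=csa,
        fascicular_fraction=frac,
        covariates=covariates,
        seed=seed,
    )


# --------------------------------------------------------------------------
# phantom construction
# --------------------------------------------------------------------------

def _pack_seeds(
    a: float,
    b: float,
    k: int,
    min_count: int,
    min_sep: float,
    rng: np.random.Generator,
    max_tries: int = 400,
) -> np.ndarray:
    """Rejection-sample up to ``k`` fascicle seed points inside the nerve
    ellipse (semi-axes a, b, shrunk 15% to keep seeds interior) with a
    minimum pairwise separation. Deterministic failure if fewer than
    ``min_count`` seeds fit within the retry budget."""
    seeds: list[tuple[float, float]] = []
    tries = 0
    sa, sb = 0.85 * a, 0.85 * b
    while len(seeds) < k and tries < max_tries:
        tries += 1
        u, v = rng.uniform(-sa, sa), rng.uniform(-sb, sb)
        if (u / sa) ** 2 + (v / sb) ** 2 > 1.0:
            continue
        if all((u - p) ** 2 + (v - q) ** 2 >= min_sep**2 for p, q in seeds):
            seeds.append((u, v))
    if len(seeds) < min_count:
        raise PackingError(
            f"placed only {len(seeds)}/{min_count} fascicle seeds after {max_tries} tries"
        )
    return np.array(seeds)


def build_label_map(
    subject: SubjectTruth,
    geom: GeometryConfig,
    rng: np.random.Generator,
    min_fascicles: int = 1,
) -> NerveLabelMap:
    """Render the subject's nerve geometry into an integer label volume.

    Per slice, the whole-nerve voxel set is the ``round(CSA / (dx*dy))``
    voxels of smallest elliptical radius, so the pixel-counting CSA
    matches the true CSA to within one voxel; the fascicle/epineurium
    split likewise hits the true fascicular fraction to within one voxel
    (epineurium voxels are those closest to fascicle-territory borders or
    to the nerve edge).
    """
    nx, ny, ns = geom.shape
    dx, dy, _ = geom.voxel_mm
    pixel_area = dx * dy

    n_nerve = int(round(subject.csa_mm2 / pixel_area))
    if n_nerve < 1:
        raise ValueError(f"CSA {subject.csa_mm2} mm^2 renders to zero voxels")

    r0 = math.sqrt(subject.csa_mm2 / math.pi)
    ratio = rng.uniform(1.0, 1.5)
    a, b = r0 * math.sqrt(ratio), r0 / math.sqrt(ratio)
    ext_x, ext_y = geom.inplane_extent_mm
    if 2 * a > 0.9 * min(ext_x, ext_y) or n_nerve > nx * ny:
        raise ValueError(
            f"requested CSA {subject.csa_mm2:.1f} mm^2 (semi-axis {a:.1f} mm) "
            f"does not fit the {ext_x:.0f} x {ext_y:.0f} mm grid"
        )
    lo, hi = geom.semi_axis_range_mm
    a, b = min(max(a, lo), hi), min(max(b, lo), hi)
    theta = rng.uniform(0.0, math.pi)

    cx0 = ext_x / 2 + rng.uniform(-geom.center_jitter_mm, geom.center_jitter_mm)
    cy0 = ext_y / 2 + rng.uniform(-geom.center_jitter_mm, geom.center_jitter_mm)

    k = int(rng.integers(geom.fascicle_count_range[0], geom.fascicle_count_range[1] + 1))
    # separation shrinks with the nerve so small nerves still hold >1 fascicle
    min_sep = min(2.0 * geom.fascicle_radius_range_mm[0], 0.7 * 0.85 * min(a, b))
    seeds = _pack_seeds(a, b, k, min_fascicles, min_sep, rng)

    n_fasc = int(round(subject.fascicular_fraction * n_nerve))
    n_epi = n_nerve - n_fasc

    xs = (np.arange(nx) + 0.5) * dx
    ys = (np.arange(ny) + 0.5) * dy
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    ct, st = math.cos(theta), math.sin(theta)

    labels = np.zeros((nx, ny, ns), dtype=np.int16)
    slice_jitter = 0.3 * geom.center_jitter_mm
    for s in range(ns):
        cx = cx0 + rng.uniform(-slice_jitter, slice_jitter)
        cy = cy0 + rng.uniform(-slice_jitter, slice_jitter)
        U = ct * (X - cx) + st * (Y - cy)
        V = -st * (X - cx) + ct * (Y - cy)
        q = (U / a) ** 2 + (V / b) ** 2
        order = np.argsort(q.ravel(), kind="stable")
        nerve_flat = order[:n_nerve]

        u = U.ravel()[nerve_flat]
        v = V.ravel()[nerve_flat]
        d = np.sqrt((u[:, None] - seeds[:, 0]) ** 2 + (v[:, None] - seeds[:, 1]) ** 2)
        if seeds.shape[0] >= 2:
            dsort = np.sort(d, axis=1)
            margin = dsort[:, 1] - dsort[:, 0]
        else:
            margin = np.full(u.shape, np.inf)
        edge = np.maximum(1.0 - np.sqrt(q.ravel()[nerve_flat]), 0.0) * min(a, b)
        score = np.minimum(margin, edge)

        epi_pick = np.argsort(score, kind="stable")[:n_epi]
        slice_labels = np.full(n_nerve, LABEL_FASCICLE, dtype=np.int16)
        slice_labels[epi_pick] = LABEL_EPINEURIUM

        flat = labels[:, :, s].ravel()
        flat[nerve_flat] = slice_labels
        labels[:, :, s] = flat.reshape(nx, ny)

    mask = NerveLabelMap(labels=labels, voxel_mm=geom.voxel_mm)

    rendered_csa = n_nerve * pixel_area
    if abs(rendered_csa - subject.csa_mm2) > 0.05 * subject.csa_mm2:
        raise RuntimeError("rendered CSA deviates more than 5% from truth")
    rendered_frac = n_fasc / n_nerve
    if abs(rendered_frac - subject.fascicular_fraction) > 0.05 * subject.fascicular_fraction:
        raise RuntimeError("rendered fascicular fraction deviates more than 5% from truth")
    return mask


def render_echoes(
    mask: NerveLabelMap,
    subject: SubjectTruth,
    acq: AcquisitionSpec,
    compartments: dict[str, CompartmentSpec] | None = None,
    rng: np.random.Generator | None = None,
) -> EchoPairVolume:
    """Render the two echo images from a label map.

    Noiseless signal per voxel: A(label) * exp(-TE / T2*(label)); the
    fascicle and epineurium T2* come from the subject truth, amplitudes
    and the muscle background from the compartment specs. The noiseless
    fascicle TE1 signal must exceed the epineurium's (hyperintense
    fascicles / hypointense epineurium).
    """
    compartments = compartments or default_compartments()
    if rng is None:
        rng = np.random.default_rng()
    amp_f = compartments["fascicle"].amplitude
    amp_e = compartments["epineurium"].amplitude
    muscle = compartments["muscle_background"]

    sig_f1 = amp_f * math.exp(-acq.te1_ms / subject.fascicle_t2star_ms)
    sig_e1 = amp_e * math.exp(-acq.te1_ms / subject.epineurium_t2star_ms)
    if not sig_f1 > sig_e1:
        raise ValueError(
            "fascicles must be hyperintense relative to the epineurium at TE1 "
            f"(got {sig_f1:.3f} <= {sig_e1:.3f}); adjust amplitudes"
        )

    amp = np.choose(mask.labels, [muscle.amplitude, amp_e, amp_f])
    t2 = np.choose(
        mask.labels,
        [muscle.t2star_ms, subject.epineurium_t2star_ms, subject.fascicle_t2star_ms],
    )
    echoes = []
    for te in (acq.te1_ms, acq.te2_ms):
        clean = amp * np.exp(-te / t2)
        if math.isinf(acq.snr):
            echoes.append(clean)
            continue
        sigma = sig_f1 / acq.snr
        if acq.noise_model == "rician":
            n1 = rng.standard_normal(clean.shape) * sigma
            n2 = rng.standard_normal(clean.shape) * sigma
            echoes.append(np.sqrt((clean + n1) ** 2 + n2**2))
        else:
            echoes.append(np.clip(clean + rng.standard_normal(clean.shape) * sigma, 0.0, None))
    return EchoPairVolume(
        echo1=echoes[0],
        echo2=echoes[1],
        te1_ms=acq.te1_ms,
        te2_ms=acq.te2_ms,
        voxel_mm=mask.voxel_mm,
    )


def build_phantom(
    subject: SubjectTruth,
    geom: GeometryConfig,
    acq: AcquisitionSpec,
    compartments: dict[str, CompartmentSpec] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[EchoPairVolume, NerveLabelMap]:
    """Label map plus rendered dual-echo volumes for one subject."""
    if rng is None:
        rng = np.random.default_rng()
    mask = build_label_map(subject, geom, rng)
    vol = render_echoes(mask, subject, acq, compartments, rng)
    return vol, mask


def simulate_subject(
    group: str,
    config: RunConfig,
    rng: np.random.Generator,
    subject_id: str = "",
) -> tuple[SubjectTruth, EchoPairVolume, NerveLabelMap]:
    """Draw one subject and render their phantom under one configuration."""
    truth = draw_subject(group, config.groups, config.covariates, rng, subject_id=subject_id)
    vol, mask = build_phantom(truth, config.geometry, config.acquisition, config.compartments, rng)
    return truth, vol, mask


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

def _subject_plan(n_attrv: int, n_hc: int) -> list[tuple[str, str]]:
    plan = [(GROUP_ATTRV, f"ATTRV-{i + 1:03d}") for i in range(n_attrv)]
    plan += [(GROUP_HC, f"HC-{i + 1:03d}") for i in range(n_hc)]
    return plan


def iter_cohort(
    config: RunConfig,
    with_images: bool = True,
) -> Iterator[tuple[SubjectTruth, EchoPairVolume | None, NerveLabelMap]]:
    """Deterministically iterate subjects of a configured cohort.

    Per-subject seeds are spawned from the master seed, so any subset of
    subjects is reproducible independently of the others. With
    ``with_images=False`` only truth and label maps are produced (echo
    rendering skipped), for morphometry-only workloads.
    """
    plan = _subject_plan(config.n_attrv, config.n_hc)
    ss = np.random.SeedSequence(config.master_seed)
    children = ss.spawn(len(plan))
    for (group, sid), child in zip(plan, children):
        rng = np.random.default_rng(child)
        seed_tag = int(child.generate_state(1, dtype=np.uint32)[0]) % (2**31)
        truth = draw_subject(
            group, config.groups, config.covariates, rng, subject_id=sid, seed=seed_tag
        )
        mask = build_label_map(truth, config.geometry, rng)
        vol = render_echoes(mask, truth, config.acquisition, config.compartments, rng) if with_images else None
        yield truth, vol, mask


def draw_cohort_truth(config: RunConfig) -> pd.DataFrame:
    """Truth table of a configured cohort without rendering any phantom.

    Uses the same per-subject seed spawning as :func:`iter_cohort`, so the
    truth values agree with a full imaging run of the same config.
    """
    plan = _subject_plan(config.n_attrv, config.n_hc)
    ss = np.random.SeedSequence(config.master_seed)
    rows = []
    for (group, sid), child in zip(plan, ss.spawn(len(plan))):
        rng = np.random.default_rng(child)
        seed_tag = int(child.generate_state(1, dtype=np.uint32)[0]) % (2**31)
        rows.append(
            draw_subject(group, config.groups, config.covariates, rng,
                         subject_id=sid, seed=seed_tag).as_row()
        )
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def generate_cohort(
    config: RunConfig,
    out_dir: str | Path,
    write_images: bool = True,
) -> pd.DataFrame:
    """Generate a cohort to disk: per-subject NIfTI echo volumes and label
    maps plus a truth CSV with stable column names. Returns the truth
    table. Identical configs (and master seed) reproduce byte-identical
    truth CSVs."""
    from .niftiio import save_labels, save_volume  # local import: nibabel optional at import time

    out = Path(out_dir)
    subj_dir = out / "subjects"
    subj_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for truth, vol, mask in iter_cohort(config, with_images=write_images):
        if write_images and vol is not None:
            save_volume(vol.echo1, vol.voxel_mm, subj_dir / f"{truth.subject_id}_echo1.nii.gz")
            save_volume(vol.echo2, vol.voxel_mm, subj_dir / f"{truth.subject_id}_echo2.nii.gz")
            save_labels(mask, subj_dir / f"{truth.subject_id}_labels.nii.gz")
        rows.append(truth.as_row())
    table = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "truth.csv", index=False, float_format="%.10g")
    return table


# --------------------------------------------------------------------------
# rater simulation
# --------------------------------------------------------------------------

def perturb_mask(mask: NerveLabelMap, rate: float, rng: np.random.Generator) -> NerveLabelMap:
    """Simulate a second rater by flipping labels on structure boundaries.

    Each voxel whose in-slice 4-neighbourhood contains a different label
    is, with probability ``rate``, reassigned to the label of one of its
    differing neighbours. The output remains a valid label map (the whole
    nerve is still the union of the epineurium and fascicle labels).
    """
    if not 0.0 <= rate <= 0.5:
        raise ValueError(f"flip rate must be in [0, 0.5], got {rate}")
    labels = mask.labels.copy()
    if rate == 0.0:
        return NerveLabelMap(labels=labels, voxel_mm=mask.voxel_mm)

    src = mask.labels
    nx, ny, _ = src.shape
    neighbours = []
    for axis, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
        shifted = np.roll(src, shift, axis=axis)
        # edge rows/cols wrap around; neutralise by copying the source there
        if axis == 0:
            idx = 0 if shift == 1 else nx - 1
            shifted[idx, :, :] = src[idx, :, :]
        else:
            idx = 0 if shift == 1 else ny - 1
            shifted[:, idx, :] = src[:, idx, :]
        neighbours.append(shifted)
    nb = np.stack(neighbours)  # (4, nx, ny, ns)
    differs = nb != src[None]
    boundary = differs.any(axis=0)
    flip = boundary & (rng.random(src.shape) < rate)

    coords = np.argwhere(flip)
    for x, y, s in coords:
        options = nb[:, x, y, s][differs[:, x, y, s]]
        labels[x, y, s] = options[rng.integers(len(options))]
    return NerveLabelMap(labels=labels, voxel_mm=mask.voxel_mm)
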