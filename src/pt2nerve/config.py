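"""Configuration dataclasses for the simulation and analysis pipeline.

Defaults encode the acquisition geometry of a dual-echo variable-echo-time
(vTE) gradient-echo protocol at 3 T (TE1/TE2 = 1.05/5.37 ms, voxel size
0.6 x 0.6 x 5.0 mm, 12 slices) and cohort-level calibration targets for
hereditary transthyretin amyloidosis (ATTRv) patients versus healthy
controls (HC): fascicle pseudo-T2*, whole-nerve cross-sectional area and
the fascicular area fraction of the nerve.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

GROUP_ATTRV = "ATTRv"
GROUP_HC = "HC"
KNOWN_GROUPS = (GROUP_ATTRV, GROUP_HC)

LABEL_BACKGROUND = 0
LABEL_EPINEURIUM = 1
LABEL_FASCICLE = 2
NERVE_LABELS = frozenset({LABEL_EPINEURIUM, LABEL_FASCICLE})


@dataclass(frozen=True)
class CompartmentSpec:
    """A tissue compartment with mono-exponential transverse decay.

    ``amplitude`` is the signal at TE = 0 in arbitrary units; it absorbs
    proton density and T1/TR/flip-angle weighting, which a two-point
    ratio estimator never sees.
    """

    name: str
    t2star_ms: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.t2star_ms <= 0:
            raise ValueError(f"t2star must be positive, got {self.t2star_ms}")
        if self.amplitude <= 0:
            raise ValueError(f"amplitude must be positive, got {self.amplitude}")

    def signal(self, te_ms: float) -> float:
        return self.amplitude * math.exp(-te_ms / self.t2star_ms)


def default_compartments() -> dict[str, CompartmentSpec]:
    """Nominal compartments: hyperintense fascicles, hypointense inner
    epineurium, and a muscle background (fat is assumed suppressed by the
    binomial excitation of the sequence and is not simulated)."""
    return {
        "fascicle": CompartmentSpec("fascicle", t2star_ms=18.0, amplitude=1.0),
        "epineurium": CompartmentSpec("epineurium", t2star_ms=9.0, amplitude=0.55),
        "muscle_background": CompartmentSpec("muscle_background", t2star_ms=25.0, amplitude=0.35),
    }


@dataclass
class GeometryConfig:
    """Voxel grid and nerve-geometry parameters of the phantom.

    The grid is a reduced field of view around the nerve (the full-FOV
    matrix would only add background voxels); voxel dimensions and slice
    count follow the acquisition protocol.
    """

    shape: tuple[int, int, int] = (96, 96, 12)
    voxel_mm: tuple[float, float, float] = (0.6, 0.6, 5.0)
    semi_axis_range_mm: tuple[float, float] = (1.5, 9.0)
    fascicle_count_range: tuple[int, int] = (4, 9)
    fascicle_radius_range_mm: tuple[float, float] = (1.0, 2.5)
    center_jitter_mm: float = 1.0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"shape must be three positive ints, got {self.shape}")
        self.shape = tuple(int(s) for s in self.shape)
        if self.shape[2] < 3:
            raise ValueError("at least 3 slices are required (first and last are excluded)")
        if any(v <= 0 for v in self.voxel_mm):
            raise ValueError(f"voxel dims must be positive, got {self.voxel_mm}")
        lo, hi = self.semi_axis_range_mm
        if not (0 < lo <= hi):
            raise ValueError("invalid semi-axis range")
        if self.fascicle_count_range[0] < 1 or self.fascicle_count_range[0] > self.fascicle_count_range[1]:
            raise ValueError("invalid fascicle count range")
        rlo, rhi = self.fascicle_radius_range_mm
        if not (0 < rlo <= rhi):
            raise ValueError("invalid fascicle radius range")
        if self.center_jitter_mm < 0:
            raise ValueError("jitter must be non-negative")

    @property
    def nslices(self) -> int:
        return self.shape[2]

    @property
    def slab_thickness_mm(self) -> float:
        """Longitudinal coverage of the acquisition (slice count x slice
        thickness); 12 x 5.0 mm = 60 mm = 6 cm for the default protocol."""
        return self.shape[2] * self.voxel_mm[2]

    @property
    def inplane_extent_mm(self) -> tuple[float, float]:
        return (self.shape[0] * self.voxel_mm[0], self.shape[1] * self.voxel_mm[1])


@dataclass
class AcquisitionSpec:
    """Echo times and noise model of the dual-echo acquisition.

    ``snr`` is the ratio of the noiseless fascicle signal at TE1 to the
    noise sigma; ``math.inf`` disables noise. Rician noise is the default
    (magnitude MRI); Gaussian is available for analytic checks.
    """

    te1_ms: float = 1.05
    te2_ms: float = 5.37
    snr: float = 50.0
    noise_model: str = "rician"

    def __post_init__(self) -> None:
        if not (0 < self.te1_ms < self.te2_ms):
            raise ValueError(f"need 0 < te1 < te2, got {self.te1_ms}, {self.te2_ms}")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.noise_model not in ("rician", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    @property
    def delta_te_ms(self) -> float:
        return self.te2_ms - self.te1_ms


@dataclass(frozen=True)
class NormalSpec:
    """Normal distribution truncated symmetrically about its mean so the
    truncated mean equals ``mean`` exactly: the truncation half-width is
    ``min(mean - floor, ceil - mean)`` (the ceiling, when given, keeps
    bounded quantities such as area fractions inside their range)."""

    mean: float
    sd: float
    floor: float = 1e-6
    ceil: float | None = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.mean <= 0:
            raise ValueError("mean must be positive")
        if self.floor > self.mean + 6 * self.sd:
            raise ValueError("infeasible truncation: floor above mean + 6 sd")
        if self.ceil is not None and self.ceil <= self.mean:
            raise ValueError("ceil must exceed the mean")


@dataclass
class GroupDistributions:
    """Per-group calibration of the subject-level truth distributions."""

    fascicle_t2star: NormalSpec
    epineurium_t2star: NormalSpec
    csa_mm2: NormalSpec
    fascicular_fraction: NormalSpec

    def __post_init__(self) -> None:
        f = self.fascicular_fraction
        if not (0 < f.mean < 1):
            raise ValueError("fascicular fraction mean must be in (0, 1)")


def default_group_distributions() -> dict[str, GroupDistributions]:
    """Cohort calibration.

    Fascicle pT2* and CSA use the published group means/SDs; the
    fascicular fraction mean is the ratio of the published fascicular
    area to CSA per group (so that the expected fascicular area of the
    simulated cohort matches the published mean under independence), with
    an SD of 0.05 chosen to reproduce the published fascicular-area
    spread. Epineurium pT2* is N(9, 2^2) ms in both groups: no group
    effect was reported for the epineurium, and no epineurium pT2* means
    were published.
    """
    return {
        GROUP_ATTRV: GroupDistributions(
            fascicle_t2star=NormalSpec(18.35, 3.48, floor=1.0),
            epineurium_t2star=NormalSpec(9.0, 2.0, floor=1.0),
            csa_mm2=NormalSpec(49.32, 19.63, floor=10.0),
            fascicular_fraction=NormalSpec(41.53 / 49.32, 0.05, floor=0.05, ceil=0.95),
        ),
        GROUP_HC: GroupDistributions(
            fascicle_t2star=NormalSpec(14.74, 3.21, floor=1.0),
            epineurium_t2star=NormalSpec(9.0, 2.0, floor=1.0),
            csa_mm2=NormalSpec(37.89, 12.92, floor=10.0),
            fascicular_fraction=NormalSpec(28.91 / 37.89, 0.05, floor=0.05, ceil=0.95),
        ),
    }


@dataclass(frozen=True)
class Marginal:
    """Marginal distribution of one covariate, expressed as an inverse-CDF
    transform of a uniform variate (so a Gaussian copula over the latent
    normals induces the configured rank correlations exactly for
    continuous, strictly monotone marginals).

    kinds:
      normal     params: mean, sd, lo (clip), hi (clip)
      lognormal  params: median, sigma (log-scale sd), hi (clip)
      binary     params: p (probability of 1)
      ordinal    params: probs (category probabilities), values
      constant   params: value
    """

    kind: str
    params: dict[str, Any]

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "lognormal", "binary", "ordinal", "constant"):
            raise ValueError(f"unknown marginal kind {self.kind!r}")
        if self.kind == "ordinal":
            probs = self.params["probs"]
            if any(p <= 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError("ordinal probs must be positive and sum to 1")
            values = self.params["values"]
            if list(values) != sorted(values) or len(set(values)) != len(values):
                raise ValueError("ordinal values (thresholds) must be strictly increasing")


@dataclass(frozen=True)
class CovariateSpec:
    """One clinical or electrophysiological covariate: per-group marginals
    and per-group target Spearman correlation with fascicle pT2*."""

    name: str
    marginals: dict[str, Marginal]
    rho_s: dict[str, float]

    def __post_init__(self) -> None:
        for g, r in self.rho_s.items():
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"rank correlation for {self.name}/{g} outside [-1, 1]: {r}")


@dataclass
class CovariateModel:
    covariates: list[CovariateSpec]

    def names(self) -> list[str]:
        return [c.name for c in self.covariates]


def default_covariate_model() -> CovariateModel:
    """Clinical scores and nerve-conduction-study (NCS) covariates.

    Patient rank-correlation targets with fascicle pT2* follow the
    published associations (NIS 0.544, NIS-LL 0.545, PND 0.592; CMAP
    peroneal -0.592, tibial -0.715; sural SNAP -0.552; NCV peroneal
    -0.519, tibial -0.531). NIS / NIS-LL marginals are lognormals with
    medians matched to the published 18 and 11, clipped to the scale
    bounds (0-244 and 0-88). PND is ordinal 1-3 with frequencies 10/6/2
    out of 18. Healthy controls score 0 on the clinical scales and have
    uncorrelated, healthier NCS marginals.
    """
    A, H = GROUP_ATTRV, GROUP_HC

    def ln(median: float, sigma: float, hi: float | None = None) -> Marginal:
        p: dict[str, Any] = {"median": median, "sigma": sigma}
        if hi is not None:
            p["hi"] = hi
        return Marginal("lognormal", p)

    def nrm(mean: float, sd: float, lo: float | None = None, hi: float | None = None) -> Marginal:
        return Marginal("normal", {"mean": mean, "sd": sd, "lo": lo, "hi": hi})

    zero = Marginal("constant", {"value": 0.0})
    covs = [
        CovariateSpec("age", {A: nrm(60.5, 8.0, lo=18.0, hi=90.0), H: nrm(55.5, 9.0, lo=18.0, hi=90.0)}, {A: 0.0, H: 0.0}),
        CovariateSpec("sex", {A: Marginal("binary", {"p": 11 / 18}), H: Marginal("binary", {"p": 14 / 21})}, {A: 0.0, H: 0.0}),
        CovariateSpec("nis", {A: ln(18.0, 0.9, hi=244.0), H: zero}, {A: 0.544, H: 0.0}),
        CovariateSpec("nis_ll", {A: ln(11.0, 0.9, hi=88.0), H: zero}, {A: 0.545, H: 0.0}),
        CovariateSpec(
            "pnd",
            {A: Marginal("ordinal", {"probs": [10 / 18, 6 / 18, 2 / 18], "values": [1, 2, 3]}), H: zero},
            {A: 0.592, H: 0.0},
        ),
        CovariateSpec("cmap_peroneal_mv", {A: ln(2.5, 0.6), H: ln(5.0, 0.35)}, {A: -0.592, H: 0.0}),
        CovariateSpec("cmap_tibial_mv", {A: ln(8.0, 0.6), H: ln(15.0, 0.35)}, {A: -0.715, H: 0.0}),
        CovariateSpec("snap_sural_uv", {A: ln(6.0, 0.7), H: ln(15.0, 0.4)}, {A: -0.552, H: 0.0}),
        CovariateSpec("ncv_peroneal_ms", {A: nrm(42.0, 4.0, lo=0.0), H: nrm(48.0, 3.0, lo=0.0)}, {A: -0.519, H: 0.0}),
        CovariateSpec("ncv_tibial_ms", {A: nrm(42.0, 4.0, lo=0.0), H: nrm(48.0, 3.0, lo=0.0)}, {A: -0.531, H: 0.0}),
    ]
    return CovariateModel(covs)


@dataclass
class AnalysisOptions:
    """Options of the analysis stages."""

    icc_variant: str = "icc2_1"
    rater_flip_rate: float = 0.2
    csa_one_tailed: bool = True
    posthoc_adjust: str = "none"  # or "holm"

    def __post_init__(self) -> None:
        if self.icc_variant not in ("icc2_1", "icc3_1"):
            raise ValueError(f"unknown ICC variant {self.icc_variant!r}")
        if not 0.0 <= self.rater_flip_rate <= 0.5:
            raise ValueError("rater flip rate must be in [0, 0.5]")
        if self.posthoc_adjust not in ("none", "holm"):
            raise ValueError("posthoc_adjust must be 'none' or 'holm'")


@dataclass
class RunConfig:
    """Full configuration of a simulated-cohort run."""

    master_seed: int
    n_attrv: int = 18
    n_hc: int = 21
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    groups: dict[str, GroupDistributions] = field(default_factory=default_group_distributions)
    covariates: CovariateModel = field(default_factory=default_covariate_model)
    compartments: dict[str, CompartmentSpec] = field(default_factory=default_compartments)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    out_dir: str = "pt2nerve_run"

    def __post_init__(self) -> None:
        if self.n_attrv < 1 or self.n_hc < 1:
            raise ValueError("cohort sizes must be >= 1")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        if "master_seed" not in raw:
            raise ValueError("config must define master_seed")
        kwargs: dict[str, Any] = {"master_seed": int(raw["master_seed"])}
        for key in ("n_attrv", "n_hc", "out_dir"):
            if key in raw:
                kwargs[key] = raw[key]
        if "geometry" in raw:
            g = dict(raw["geometry"])
            for tup in ("shape", "voxel_mm", "semi_axis_range_mm", "fascicle_count_range", "fascicle_radius_range_mm"):
                if tup in g:
                    g[tup] = tuple(g[tup])
            kwargs["geometry"] = GeometryConfig(**g)
        if "acquisition" in raw:
            a = dict(raw["acquisition"])
            if a.get("snr") in ("inf", ".inf", None):
                a["snr"] = math.inf
            kwargs["acquisition"] = AcquisitionSpec(**a)
        if "groups" in raw:
            groups = {}
            for gname, spec in raw["groups"].items():
                groups[gname] = GroupDistributions(
                    **{k: NormalSpec(**v) for k, v in spec.items()}
                )
            kwargs["groups"] = groups
        if "analysis" in raw:
            kwargs["analysis"] = AnalysisOptions(**raw["analysis"])
        return cls(**kwargs)

    def to_canonical_dict(self) -> dict[str, Any]:
        """Stable plain-type representation used for config hashing."""

        def plain(obj: Any) -> Any:
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, dict):
                return {str(k): plain(v) for k, v in sorted(obj.items(), key=lambda kv: str(kv[0]))}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, float) and math.isinf(obj):
                return "inf"
            return obj

        return plain(self)  # type: ignore[return-value]
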