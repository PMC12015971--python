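"""Pipeline orchestration: simulate -> pT2* map -> morphometry ->
reliability -> statistics, as one reproducible, logged run.

Every stage persists its outputs (NIfTI images, CSV tables, JSON
reports) and the run closes with a manifest recording the configuration
hash, software version and a SHA-256 checksum per output file, so two
runs with the same configuration can be verified identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import (
    GROUP_ATTRV,
    LABEL_EPINEURIUM,
    LABEL_FASCICLE,
    NERVE_LABELS,
    AnalysisOptions,
    RunConfig,
)
from .morphometry import NerveLabelMap, area_profile
from .relaxometry import (
    EchoPairVolume,
    compute_pt2star,
    roi_mean_pt2star,
    select_analysis_slices,
)
from .reliability import dice, icc_two_rater
from .simulate import SubjectTruth, iter_cohort, perturb_mask
from . import stats as st

log = logging.getLogger("pt2nerve")

__all__ = ["SubjectMeasures", "RunManifest", "analyze_subject", "exclude_subjects",
           "build_cohort_table", "run_statistics", "run_all"]

MEASURE_COLUMNS = [
    "fascicle_pt2star_ms",
    "epineurium_pt2star_ms",
    "whole_nerve_pt2star_ms",
    "csa_mm2",
    "fascicular_area_mm2",
    "epineurium_area_mm2",
    "valid_fraction_fascicle",
    "valid_fraction_whole_nerve",
]


@dataclass
class SubjectMeasures:
    subject_id: str
    fascicle_pt2star_ms: float
    epineurium_pt2star_ms: float
    whole_nerve_pt2star_ms: float
    csa_mm2: float
    fascicular_area_mm2: float
    epineurium_area_mm2: float
    valid_fraction_fascicle: float
    valid_fraction_whole_nerve: float

    def as_row(self) -> dict:
        return dict(self.__dict__)


@dataclass
class RunManifest:
    config_hash: str
    version: str
    started: str
    finished: str = ""
    files: dict[str, str] = field(default_factory=dict)
    stage_log: list[str] = field(default_factory=list)

    def checksum(self, path: Path, root: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        self.files[str(path.relative_to(root))] = digest

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def analyze_subject(
    vol: EchoPairVolume,
    mask: NerveLabelMap,
    subject_id: str = "",
) -> SubjectMeasures:
    """Full per-subject analysis: voxelwise pT2* map, ROI means over the
    analysis slices (first and last excluded), and sub-structure areas."""
    slices = select_analysis_slices(mask.nslices)
    pmap = compute_pt2star(vol)
    fasc = roi_mean_pt2star(pmap, mask.labels, {LABEL_FASCICLE}, slices, "fascicles")
    epi = roi_mean_pt2star(pmap, mask.labels, {LABEL_EPINEURIUM}, slices, "epineurium")
    whole = roi_mean_pt2star(pmap, mask.labels, NERVE_LABELS, slices, "whole_nerve")
    areas = area_profile(mask, slices)
    return SubjectMeasures(
        subject_id=subject_id,
        fascicle_pt2star_ms=fasc.mean_ms,
        epineurium_pt2star_ms=epi.mean_ms,
        whole_nerve_pt2star_ms=whole.mean_ms,
        csa_mm2=areas.csa_mm2,
        fascicular_area_mm2=areas.fascicular_area_mm2,
        epineurium_area_mm2=areas.epineurium_area_mm2,
        valid_fraction_fascicle=fasc.valid_fraction,
        valid_fraction_whole_nerve=whole.valid_fraction,
    )


def exclude_subjects(
    cohort: pd.DataFrame,
    flags: Mapping[str, str] | Iterable[str],
    id_col: str = "subject_id",
) -> tuple[pd.DataFrame, list[str]]:
    """Remove flagged subjects (e.g. motion artifacts) from the analysis
    set. Returns the filtered table and one log line per exclusion;
    kept + excluded = enrolled by construction."""
    if isinstance(flags, Mapping):
        reasons = dict(flags)
    else:
        reasons = {sid: "excluded" for sid in flags}
    known = set(cohort[id_col])
    unknown = sorted(set(reasons) - known)
    if unknown:
        raise ValueError(f"exclusion flags reference unknown subjects: {unknown}")
    kept = cohort[~cohort[id_col].isin(reasons)].reset_index(drop=True)
    lines = [f"excluded {sid}: {reason}" for sid, reason in sorted(reasons.items())]
    assert len(kept) + len(reasons) == len(cohort)
    for line in lines:
        log.info(line)
    return kept, lines


def build_cohort_table(
    truths: Iterable[SubjectTruth],
    measures: Iterable[SubjectMeasures],
) -> pd.DataFrame:
    """Join per-subject derived measures to the subject records."""
    t = pd.DataFrame([x.as_row() for x in truths])
    m = pd.DataFrame([x.as_row() for x in measures])
    table = t.merge(m, on="subject_id", validate="one_to_one")
    if table["subject_id"].duplicated().any():
        raise ValueError("duplicated subject ids")
    return st.add_severity_column(table)


def run_statistics(cohort: pd.DataFrame, options: AnalysisOptions) -> tuple[pd.DataFrame, str]:
    """The study-style inferential battery on a cohort table.

    Covariate-adjusted group comparisons of the pT2* measures, two-sample
    tests of the morphometric measures (CSA one-tailed larger-in-patients
    when configured), the severity ANOVA with Dunn post hoc on fascicle
    pT2*, and clinical/NCS correlations within the patient group.
    Returns a tidy results table and a Markdown report.
    """
    if len(cohort) == 0:
        raise ValueError("empty analysis set: all subjects were excluded")
    rows: list[dict] = []
    md: list[str] = ["# Group statistics report", ""]

    def record(measure: str, contrast: str, res: st.StatResult) -> None:
        row = {"measure": measure, "contrast": contrast}
        row.update(res.as_row())
        rows.append(row)
        md.append(
            f"- **{measure}** [{contrast}] {res.test}: estimate={res.estimate:.4g}, "
            f"coefficient={res.coefficient:.4g}, p={res.p_value:.4g}, n={res.n}"
        )

    for meas in ("whole_nerve_pt2star_ms", "fascicle_pt2star_ms", "epineurium_pt2star_ms"):
        record(meas, "ATTRv vs HC (age/sex adjusted)", st.adjusted_group_comparison(cohort, meas))

    for meas, one_tailed in (
        ("csa_mm2", options.csa_one_tailed),
        ("fascicular_area_mm2", False),
        ("epineurium_area_mm2", False),
    ):
        alt = "greater" if one_tailed else "two-sided"
        pair = st.two_sample_tests(cohort, meas, alternative=alt)
        record(meas, "ATTRv vs HC", pair["welch_t"])
        record(meas, "ATTRv vs HC", pair["mannwhitney_u"])

    try:
        omnibus, posthoc = st.severity_anova(cohort, "fascicle_pt2star_ms")
        record("fascicle_pt2star_ms", "HC vs mild vs moderate_severe", omnibus)
        md.append("")
        md.append("## Dunn pairwise post hoc (fascicle pT2*)")
        md.append("```\n" + posthoc.to_string(index=False) + "\n```")
        md.append("")
        for _, r in posthoc.iterrows():
            rows.append(
                {
                    "measure": "fascicle_pt2star_ms",
                    "contrast": f"{r['group_a']} vs {r['group_b']} (Dunn)",
                    "test": "Dunn z",
                    "estimate": r["z"],
                    "coefficient": r["z"],
                    "p": r["p_holm"] if options.posthoc_adjust == "holm" else r["p_unadjusted"],
                    "n": omnibus.n,
                    "covariates": "",
                }
            )
    except ValueError as err:
        md.append(f"- severity ANOVA skipped: {err}")

    patients = cohort[cohort["group"] == GROUP_ATTRV]
    covs = patients[["age", "sex"]].to_numpy(dtype=float) if len(patients) >= 6 else None
    clinical = [("nis", "pearson"), ("nis_ll", "pearson"), ("pnd", "spearman")]
    ncs = [
        ("cmap_peroneal_mv", "spearman"),
        ("cmap_tibial_mv", "spearman"),
        ("snap_sural_uv", "spearman"),
        ("ncv_peroneal_ms", "spearman"),
        ("ncv_tibial_ms", "spearman"),
    ]
    for col, method in clinical + ncs:
        try:
            res = st.correlate(
                patients["fascicle_pt2star_ms"], patients[col], method=method,
                covariates=covs if col in dict(clinical) else None,
            )
        except ValueError as err:
            md.append(f"- correlation fascicle pT2* vs {col} skipped: {err}")
            continue
        record("fascicle_pt2star_ms", f"vs {col} (patients)", res)

    res = st.correlate(cohort["fascicular_area_mm2"], cohort["fascicle_pt2star_ms"], method="spearman")
    record("fascicular_area_mm2", "vs fascicle pT2* (all)", res)

    return pd.DataFrame(rows), "\n".join(md) + "\n"


def run_all(config: RunConfig, out_dir: str | Path | None = None,
            exclusions: Mapping[str, str] | None = None) -> RunManifest:
    """Execute all stages in order and persist every intermediate.

    Writes per-subject NIfTI volumes and label maps, the truth CSV, the
    cohort table (truth + derived measures), a reliability report against
    a simulated second rater, the statistics tables, and a manifest with
    per-file checksums.
    """
    from .niftiio import save_labels, save_pt2star_map, save_volume

    out = Path(out_dir) if out_dir is not None else Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subj_dir = out / "subjects"
    subj_dir.mkdir(exist_ok=True)

    manifest = RunManifest(
        config_hash=hashlib.sha256(
            yaml.safe_dump(config.to_canonical_dict(), sort_keys=True).encode()
        ).hexdigest(),
        version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_canonical_dict(), sort_keys=True))

    rater_rng = np.random.default_rng(np.random.SeedSequence([config.master_seed, 2**20]))
    truths: list[SubjectTruth] = []
    measures: list[SubjectMeasures] = []
    rater_a: dict[str, SubjectMeasures] = {}
    rater_b: dict[str, SubjectMeasures] = {}
    dice_scores: dict[str, list[float]] = {"whole_nerve": [], "fascicles": [], "epineurium": []}

    for truth, vol, mask in iter_cohort(config, with_images=True):
        assert vol is not None
        sid = truth.subject_id
        save_volume(vol.echo1, vol.voxel_mm, subj_dir / f"{sid}_echo1.nii.gz")
        save_volume(vol.echo2, vol.voxel_mm, subj_dir / f"{sid}_echo2.nii.gz")
        save_labels(mask, subj_dir / f"{sid}_labels.nii.gz")
        pmap = compute_pt2star(vol)
        save_pt2star_map(pmap, subj_dir / f"{sid}_pt2star.nii.gz", subj_dir / f"{sid}_valid.nii.gz")

        m = analyze_subject(vol, mask, sid)
        truths.append(truth)
        measures.append(m)
        rater_a[sid] = m
        log.info(
            "subject %s: fascicle pT2*=%.2f ms, valid fraction=%.3f",
            sid, m.fascicle_pt2star_ms, m.valid_fraction_fascicle,
        )

        mask_b = perturb_mask(mask, config.analysis.rater_flip_rate, rater_rng)
        rater_b[sid] = analyze_subject(vol, mask_b, sid)
        dice_scores["whole_nerve"].append(dice(mask, mask_b, NERVE_LABELS))
        dice_scores["fascicles"].append(dice(mask, mask_b, {LABEL_FASCICLE}))
        dice_scores["epineurium"].append(dice(mask, mask_b, {LABEL_EPINEURIUM}))
    manifest.stage_log.append(f"simulate+map: {len(truths)} subjects")

    truth_table = pd.DataFrame([t.as_row() for t in truths])
    truth_table.to_csv(out / "truth.csv", index=False, float_format="%.10g")
    cohort = build_cohort_table(truths, measures)
    if exclusions:
        cohort, lines = exclude_subjects(cohort, exclusions)
        manifest.stage_log.extend(lines)
    cohort.to_csv(out / "cohort.csv", index=False, float_format="%.10g")
    manifest.stage_log.append(
        f"cohort: {len(cohort)} analyzed of {len(truths)} enrolled"
    )

    ids = sorted(rater_a)
    icc_report = {}
    for meas in ("fascicle_pt2star_ms", "csa_mm2", "fascicular_area_mm2"):
        tab = np.array(
            [[getattr(rater_a[i], meas), getattr(rater_b[i], meas)] for i in ids]
        )
        icc = icc_two_rater(tab, config.analysis.icc_variant)
        icc_report[meas] = {"icc": icc.value, "variant": icc.variant, "n": icc.n_subjects}
    reliability = {
        "dice": {k: float(np.mean(v)) for k, v in dice_scores.items()},
        "icc": icc_report,
        "rater_flip_rate": config.analysis.rater_flip_rate,
    }
    (out / "reliability.json").write_text(json.dumps(reliability, indent=2, sort_keys=True))
    manifest.stage_log.append("reliability: done")

    results, report_md = run_statistics(cohort, config.analysis)
    results.to_csv(out / "stats_results.csv", index=False, float_format="%.10g")
    (out / "stats_report.md").write_text(report_md)
    manifest.stage_log.append(f"stats: {len(results)} tests")

    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest.checksum(path, out)
    manifest.write(out / "manifest.json")
    return manifest
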