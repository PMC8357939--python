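"""End-to-end study orchestration: simulate -> consensus -> extract -> ICC.

``run_pipeline`` executes the whole analysis from a single
:class:`PipelineConfig` and master seed, deterministically: generate (or
load) the cohort, build per-patient STAPLE consensus volumes and Dice
agreement records, extract the radiomic panel for every (patient, observer)
mask, and compute the ICC(2,1) robustness tables with discipline
comparisons. All report tables are plain delimited text with fixed float
formatting, so identical (config, seed) runs produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .consensus import compare_disciplines_dsc, compare_volumes, per_patient_agreement
from .features import ExtractionConfig, build_filter_bank, extract_from_bank
from .image_model import read_mask, read_volume, resample_isotropic
from .robustness import (
    DEFAULT_ICC_THRESHOLD,
    discipline_icc_wilcoxon,
    feature_icc_table,
    rank_agreement,
    robust_summary,
    top_features,
)
from .synthetic_cohort import (
    CohortConfig,
    ObserverProfile,
    PatientCase,
    StudyCohort,
    generate_cohort,
)

__all__ = [
    "PipelineConfig",
    "ReportBundle",
    "extract_cohort_features",
    "run_pipeline",
    "run_on_external",
    "load_cohort_from_manifest",
]

logger = logging.getLogger("segrobust")

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full study run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    staple_tol: float = 1e-6
    staple_max_iter: int = 100
    icc_threshold: float = DEFAULT_ICC_THRESHOLD
    top_k: int = 3

    def with_seed(self, master_seed: int) -> "PipelineConfig":
        return dataclasses.replace(
            self, cohort=dataclasses.replace(self.cohort, master_seed=master_seed)
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        cohort = dict(data.pop("cohort", {}))
        observers = cohort.pop("observers", None)
        if observers is not None:
            cohort["observers"] = tuple(
                o if isinstance(o, ObserverProfile) else ObserverProfile(**o)
                for o in observers
            )
        for key in ("native_spacing", "grid_shape"):
            if key in cohort:
                cohort[key] = tuple(cohort[key])
        extraction = dict(data.pop("extraction", {}))
        if "filters" in extraction:
            extraction["filters"] = tuple(extraction["filters"])
        return cls(
            cohort=CohortConfig(**cohort),
            extraction=ExtractionConfig(**extraction),
            **data,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class ReportBundle:
    """All report tables of one run, cross-referencing one cohort manifest."""

    agreement_records: pd.DataFrame
    agreement_summary: pd.DataFrame
    dsc_comparison: dict
    volume_comparison: dict
    features: pd.DataFrame
    icc_records: pd.DataFrame
    robust_table: pd.DataFrame
    robust_info: dict
    top_features: pd.DataFrame
    wilcoxon: pd.DataFrame
    rank_agreement: pd.DataFrame
    run_manifest: dict

    _TABLES = (
        "agreement_records", "agreement_summary", "features", "icc_records",
        "robust_table", "top_features", "wilcoxon", "rank_agreement",
    )

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            df: pd.DataFrame = getattr(self, name)
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
        scalars = {
            "dsc_comparison": self.dsc_comparison,
            "volume_comparison": self.volume_comparison,
            "robust_info": self.robust_info,
            "run_manifest": self.run_manifest,
        }
        with open(out / "summary.json", "w") as fh:
            json.dump(scalars, fh, indent=2, sort_keys=True, default=float)
            fh.write("\n")


def extract_cohort_features(
    cohort: StudyCohort, config: ExtractionConfig | None = None
) -> pd.DataFrame:
    """Radiomic panel for every (patient, observer) mask of a cohort.

    The image is resampled and filtered once per patient; each observer
    mask is resampled and fed through the shared filter bank, which matches
    :func:`segrobust.features.extract_panel` exactly while avoiding
    redundant filtering.
    """
    config = config or ExtractionConfig()
    frames = []
    for case in cohort.patients:
        t0 = time.perf_counter()
        rs_img = resample_isotropic(case.image, config.target_spacing, "image")
        bank = build_filter_bank(rs_img, config)
        for obs_id in sorted(case.observer_masks):
            rs_mask = resample_isotropic(case.observer_masks[obs_id], config.target_spacing)
            if rs_mask.voxel_count == 0:
                raise ValueError(
                    f"patient {case.patient_id}, observer {obs_id}: mask is empty "
                    "after resampling"
                )
            df = extract_from_bank(bank, rs_mask, config)
            df.insert(0, "observer_id", obs_id)
            df.insert(0, "patient_id", case.patient_id)
            frames.append(df)
        logger.debug(
            "extracted %s in %.2fs", case.patient_id, time.perf_counter() - t0
        )
    return pd.concat(frames, ignore_index=True)


def _analyze(cohort: StudyCohort, config: PipelineConfig, features: pd.DataFrame | None = None) -> ReportBundle:
    stage0 = time.perf_counter()
    records, summary, _ = per_patient_agreement(
        cohort, tol=config.staple_tol, max_iter=config.staple_max_iter
    )
    disciplines = sorted({p.discipline for p in cohort.config.observers})
    two_groups = len(disciplines) == 2
    dsc_cmp = compare_disciplines_dsc(records) if two_groups and len(cohort.patients) > 1 else {}
    vol_cmp = compare_volumes(cohort) if two_groups else {}
    logger.info("consensus/agreement stage: %.1fs", time.perf_counter() - stage0)

    stage1 = time.perf_counter()
    if features is None:
        features = extract_cohort_features(cohort, config.extraction)
    logger.info("feature extraction stage: %.1fs", time.perf_counter() - stage1)

    stage2 = time.perf_counter()
    groups = {p.observer_id: p.discipline for p in cohort.config.observers}
    icc_records = feature_icc_table(features, groups, threshold=config.icc_threshold)
    robust_table, robust_info = robust_summary(icc_records)
    tops = pd.concat(
        [
            top_features(icc_records, g, config.top_k).assign(group=g)
            for g in ["all"] + disciplines
        ],
        ignore_index=True,
    )
    if two_groups:
        wcx = discipline_icc_wilcoxon(icc_records, *disciplines)
        ranks = rank_agreement(icc_records, *disciplines)
    else:
        wcx = pd.DataFrame(columns=["filter", "n_pairs", "statistic", "p_value"])
        ranks = pd.DataFrame(columns=["feature_class", "n_features", "slope", "r_squared"])
    logger.info("robustness stage: %.1fs", time.perf_counter() - stage2)

    import scipy

    manifest = {
        "config_hash": config.content_hash(),
        "master_seed": cohort.config.master_seed,
        "n_patients": len(cohort.patients),
        "observers": {p.observer_id: p.discipline for p in cohort.config.observers},
        "versions": {
            "segrobust": _pkg_version,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    return ReportBundle(
        agreement_records=records,
        agreement_summary=summary,
        dsc_comparison=dsc_cmp,
        volume_comparison=vol_cmp,
        features=features,
        icc_records=icc_records,
        robust_table=robust_table,
        robust_info=robust_info,
        top_features=tops,
        wilcoxon=wcx,
        rank_agreement=ranks,
        run_manifest=manifest,
    )


def run_pipeline(
    config: PipelineConfig | None = None,
    out_dir=None,
    resume: bool = True,
) -> ReportBundle:
    """Run the full study on a synthetic cohort.

    Deterministic given (config, master seed). When ``out_dir`` is set the
    report tables are persisted there; with ``resume`` the expensive
    feature-extraction stage is reloaded from a previous run in the same
    directory if its config hash matches.
    """
    config = config or PipelineConfig()
    t0 = time.perf_counter()
    cohort = generate_cohort(config.cohort)
    logger.info("cohort generation stage: %.1fs", time.perf_counter() - t0)

    features = None
    out = Path(out_dir) if out_dir is not None else None
    if out is not None and resume:
        feat_path = out / "features.tsv"
        summary_path = out / "summary.json"
        if feat_path.exists() and summary_path.exists():
            try:
                stored = json.load(open(summary_path))
                if stored.get("run_manifest", {}).get("config_hash") == config.content_hash():
                    features = pd.read_csv(feat_path, sep="\t")
                    logger.info("resumed feature table from %s", feat_path)
            except (json.JSONDecodeError, KeyError):  # pragma: no cover
                features = None

    bundle = _analyze(cohort, config, features)
    if out is not None:
        bundle.write(out)
    return bundle


# ---------------------------------------------------------------------------
# External cohorts via manifest
# ---------------------------------------------------------------------------

_MANIFEST_COLUMNS = ("patient_id", "observer_id", "discipline", "image_path", "mask_path")


def load_cohort_from_manifest(manifest: "pd.DataFrame | str | Path") -> StudyCohort:
    """Load a user-supplied cohort of NIfTI images/masks from a manifest.

    The manifest is a delimited table with columns patient_id, observer_id,
    discipline, image_path, mask_path (rows with observer_id ``__truth__``
    are treated as ground truth and optional). All validation problems are
    enumerated before any heavy computation.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest, sep="\t")
    missing_cols = [c for c in _MANIFEST_COLUMNS if c not in manifest.columns]
    if missing_cols:
        raise ValueError(f"manifest lacks columns {missing_cols}")

    obs_rows = manifest[manifest["observer_id"] != "__truth__"]
    problems: list[str] = []
    observer_sets = obs_rows.groupby("patient_id")["observer_id"].apply(set)
    all_obs = set().union(*observer_sets) if len(observer_sets) else set()
    for pid, obs in observer_sets.items():
        gap = all_obs - obs
        if gap:
            problems.append(f"patient {pid}: missing observers {sorted(gap)}")
    disc = obs_rows.drop_duplicates("observer_id").set_index("observer_id")["discipline"]
    for _, row in manifest.iterrows():
        for col in ("image_path", "mask_path"):
            if not Path(row[col]).exists():
                problems.append(f"{row['patient_id']}/{row['observer_id']}: missing {row[col]}")
    if problems:
        raise ValueError("manifest validation failed:\n  " + "\n  ".join(problems))

    patients = []
    for pid, rows in manifest.groupby("patient_id", sort=True):
        image = read_volume(rows.iloc[0]["image_path"])
        truth = None
        masks = {}
        for _, row in rows.iterrows():
            mask = read_mask(row["mask_path"])
            if not mask.same_geometry(image):
                problems.append(
                    f"{pid}/{row['observer_id']}: mask geometry {mask.shape} does not "
                    f"match image {image.shape}"
                )
                continue
            if row["observer_id"] == "__truth__":
                truth = mask
            else:
                masks[row["observer_id"]] = mask
        patients.append(PatientCase(str(pid), image, truth if truth is not None else next(iter(masks.values())), masks))
    if problems:
        raise ValueError("manifest validation failed:\n  " + "\n  ".join(problems))

    profiles = tuple(
        ObserverProfile(observer_id=o, discipline=str(disc[o])) for o in sorted(all_obs)
    )
    n_patients = len(patients)
    cfg = CohortConfig(n_patients=n_patients, observers=profiles)
    return StudyCohort(patients, cfg)


def run_on_external(
    manifest, config: PipelineConfig | None = None, out_dir=None
) -> ReportBundle:
    """Run consensus, extraction and robustness on a user-supplied cohort."""
    config = config or PipelineConfig()
    cohort = load_cohort_from_manifest(manifest)
    bundle = _analyze(cohort, config)
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
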