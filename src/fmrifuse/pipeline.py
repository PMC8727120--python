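"""End-to-end orchestration: BOLD series -> mALFF + mReHo maps -> PCANet
features per modality -> CCA fusion -> SVM, evaluated by stratified k-fold
cross-validation.

The maps are deterministic per subject and are computed once; everything
that *learns* from data (both PCANet filter banks, the CCA projections and
the SVM) is fitted inside each training fold only and applied unchanged to
the held-out fold, so the pooled metrics are leak-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alff import FrequencyBand, malff_map
from .cca import fit_cca, transform_fuse
from .classify import (
    ConfusionCounts,
    MetricsReport,
    SVMConfig,
    confusion,
    metrics,
    stratified_folds,
    train_svm,
)
from .pcanet import PCANet3D, PCANetParams
from .reho import mreho_map, neighborhood_offsets
from .synthetic import PhantomConfig, make_cohort
from .volumes import BrainMask, Volume3D, auto_mask, drop_initial_volumes, read_volume4d

__all__ = [
    "PipelineConfig",
    "SubjectMaps",
    "compute_subject_maps",
    "load_manifest_cohort",
    "cross_validate_maps",
    "run_pipeline",
    "run_single_modality",
]

MODALITIES = ("malff", "mreho")
FUSION_MODES = ("cca", "tandem", "malff", "mreho")


@dataclass(frozen=True)
class PipelineConfig:
    """Every knob of the end-to-end run, with logged defaults."""

    band: FrequencyBand = field(default_factory=FrequencyBand)
    reho_band: FrequencyBand | None = field(default_factory=FrequencyBand)
    neighbors: int = 26
    fwhm_mm: float = 4.0
    drop_initial: int = 10
    # after two pool-by-2 stages a 16^3 map is 4^3; edge-2 blocks tile it into
    # the 8 histogram blocks used by default
    pcanet: PCANetParams = field(default_factory=lambda: PCANetParams(hist_block=2, beta=8))
    cca_components: int | None = None
    cca_ridge: float = 1e-3
    cca_pca_dim: int | None = None
    fusion_mode: str = "concat"
    svm: SVMConfig = field(default_factory=SVMConfig)
    n_folds: int = 5
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a YAML or JSON config file; keyword overrides win.

        Recognized keys mirror the dataclass fields; ``band``/``reho_band``
        are two-element [f_low, f_high] lists (``reho_band: null`` ranks raw
        series), ``pcanet`` and ``svm`` are nested mappings.
        """
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        raw.update(overrides)
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(raw.get("band"), (list, tuple)):
            raw["band"] = FrequencyBand(*raw["band"])
        if isinstance(raw.get("reho_band"), (list, tuple)):
            raw["reho_band"] = FrequencyBand(*raw["reho_band"])
        if isinstance(raw.get("pcanet"), dict):
            raw["pcanet"] = PCANetParams(**raw["pcanet"])
        if isinstance(raw.get("svm"), dict):
            raw["svm"] = SVMConfig(**raw["svm"])
        return cls(**raw)

    def resolved(self) -> dict:
        """The effective configuration, for echoing into output artifacts."""
        d = asdict(self)
        d["band"] = [self.band.f_low, self.band.f_high]
        d["reho_band"] = (
            None if self.reho_band is None else [self.reho_band.f_low, self.reho_band.f_high]
        )
        return d


@dataclass(frozen=True)
class SubjectMaps:
    """Per-subject inputs to the learning stages."""

    subject_id: str
    label: str
    malff: Volume3D
    mreho: Volume3D


def compute_subject_maps(
    cohort: Sequence[tuple[str, str, "Volume4D"]],
    cfg: PipelineConfig,
    mask: BrainMask | None = None,
) -> list[SubjectMaps]:
    """Drop unstable frames and compute the mALFF and mReHo map per subject."""
    scheme = neighborhood_offsets(cfg.neighbors)
    out = []
    for subject_id, label, vol in cohort:
        try:
            v = drop_initial_volumes(vol, cfg.drop_initial)
            m = mask if mask is not None else auto_mask(v)
            malff = malff_map(v, m, cfg.band)
            mreho = mreho_map(v, m, scheme, band=cfg.reho_band, fwhm_mm=cfg.fwhm_mm)
        except Exception as exc:
            raise RuntimeError(f"map computation failed for subject {subject_id}: {exc}") from exc
        out.append(SubjectMaps(subject_id=subject_id, label=label, malff=malff, mreho=mreho))
    return out


def load_manifest_cohort(manifest: str | Path, tr_seconds: float | None = None):
    """Read a subject table CSV (subject_id, label, path) into a cohort list."""
    manifest = Path(manifest)
    table = pd.read_csv(manifest)
    required = {"subject_id", "label", "path"}
    if not required.issubset(table.columns):
        raise ValueError(f"manifest needs columns {sorted(required)}, has {list(table.columns)}")
    cohort = []
    for row in table.itertuples():
        path = Path(row.path)
        if not path.is_absolute():
            path = manifest.parent / path
        try:
            vol = read_volume4d(path, tr_seconds=tr_seconds)
        except FileNotFoundError as exc:
            raise FileNotFoundError(f"subject {row.subject_id}: {exc}") from exc
        cohort.append((str(row.subject_id), str(row.label), vol))
    return cohort


def _positive_label(labels: np.ndarray):
    """Deterministic positive class: the lexicographically last label."""
    return np.unique(labels)[-1]


def _fold_features(
    maps: Sequence[SubjectMaps], train_idx: np.ndarray, test_idx: np.ndarray,
    cfg: PipelineConfig, mode: str,
) -> tuple[np.ndarray, np.ndarray]:
    """PCANet (+ optional CCA) features for one fold; all fitting on train only."""
    feats: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    needed = MODALITIES if mode in ("cca", "tandem") else (mode,)
    for modality in needed:
        images = [getattr(s, modality) for s in maps]
        net = PCANet3D(params=cfg.pcanet)
        net.fit([images[i] for i in train_idx])
        feats[modality] = (
            net.transform([images[i] for i in train_idx]),
            net.transform([images[i] for i in test_idx]),
        )
    if mode == "cca":
        model = fit_cca(
            feats["malff"][0], feats["mreho"][0],
            n_components=cfg.cca_components, ridge=cfg.cca_ridge, pca_dim=cfg.cca_pca_dim,
        )
        train = transform_fuse(model, feats["malff"][0], feats["mreho"][0], cfg.fusion_mode)
        test = transform_fuse(model, feats["malff"][1], feats["mreho"][1], cfg.fusion_mode)
    elif mode == "tandem":
        train = np.hstack([feats["malff"][0], feats["mreho"][0]])
        test = np.hstack([feats["malff"][1], feats["mreho"][1]])
    else:
        train, test = feats[mode]
    return train, test


def cross_validate_maps(
    maps: Sequence[SubjectMaps], cfg: PipelineConfig, mode: str = "cca"
) -> tuple[MetricsReport, list[dict]]:
    """Stratified k-fold CV of one pipeline arm over precomputed maps.

    ``mode``: 'cca' (fused), 'tandem' (plain concatenation of the two
    feature matrices), or a single modality 'malff'/'mreho'. Returns pooled
    metrics plus per-fold detail.
    """
    if mode not in FUSION_MODES:
        raise ValueError(f"mode must be one of {FUSION_MODES}, got {mode!r}")
    labels = np.asarray([s.label for s in maps])
    folds = stratified_folds(labels, cfg.n_folds, cfg.seed)
    all_idx = np.arange(len(maps))
    positive = _positive_label(labels)
    pooled_true: list = []
    pooled_pred: list = []
    pooled_scores: list[float] = []
    fold_detail = []
    for fold_no, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        train_x, test_x = _fold_features(maps, train_idx, test_idx, cfg, mode)
        clf = train_svm(train_x, labels[train_idx], cfg.svm)
        pred = clf.predict(test_x)
        scores = clf.decision_function(test_x)
        if scores.ndim > 1:  # one-vs-one multiclass: no single ROC score
            scores = np.full(len(test_idx), np.nan)
        if clf.classes_[-1] != positive:
            scores = -scores
        pooled_true.extend(labels[test_idx])
        pooled_pred.extend(pred)
        pooled_scores.extend(np.asarray(scores, dtype=np.float64))
        fold_detail.append(
            {
                "fold": fold_no,
                "test_subjects": [maps[i].subject_id for i in test_idx],
                "accuracy": float(np.mean(pred == labels[test_idx])),
            }
        )
    counts = confusion(pooled_true, pooled_pred, positive)
    scores_arr = np.asarray(pooled_scores)
    use_scores = not np.isnan(scores_arr).any()
    report = metrics(
        counts,
        y_true=pooled_true if use_scores else None,
        scores=scores_arr if use_scores else None,
        positive_label=positive,
    )
    return report, fold_detail


def run_pipeline(
    cohort_or_manifest,
    cfg: PipelineConfig = PipelineConfig(),
    mask: BrainMask | None = None,
    out_dir: str | Path | None = None,
) -> tuple[MetricsReport, list[dict]]:
    """Full fused pipeline on a cohort list or a manifest CSV path."""
    cohort = _resolve_cohort(cohort_or_manifest)
    maps = compute_subject_maps(cohort, cfg, mask)
    report, detail = cross_validate_maps(maps, cfg, mode="cca")
    if out_dir is not None:
        _persist(out_dir, cfg, report, detail)
    return report, detail


def run_single_modality(
    cohort_or_manifest,
    modality: str,
    cfg: PipelineConfig = PipelineConfig(),
    mask: BrainMask | None = None,
) -> tuple[MetricsReport, list[dict]]:
    """Single-stream arm ('malff' or 'mreho') or the 'tandem' concatenation."""
    if modality not in ("malff", "mreho", "tandem"):
        raise ValueError(f"modality must be 'malff', 'mreho' or 'tandem', got {modality!r}")
    cohort = _resolve_cohort(cohort_or_manifest)
    maps = compute_subject_maps(cohort, cfg, mask)
    return cross_validate_maps(maps, cfg, mode=modality)


def _resolve_cohort(cohort_or_manifest):
    if isinstance(cohort_or_manifest, (str, Path)):
        return load_manifest_cohort(cohort_or_manifest)
    return list(cohort_or_manifest)


def _persist(out_dir: str | Path, cfg: PipelineConfig,
             report: MetricsReport, detail: list[dict]) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "config.json").write_text(json.dumps(cfg.resolved(), indent=2, default=str))
    (out_dir / "metrics.json").write_text(
        json.dumps({"pooled": report.as_dict(), "folds": detail}, indent=2)
    )


def phantom_cohort(cfg: PhantomConfig | None = None):
    """Convenience: the default strong-effect phantom cohort (in memory)."""
    return make_cohort(cfg or PhantomConfig())
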