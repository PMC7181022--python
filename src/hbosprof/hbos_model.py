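"""Histogram-based outlier score (HBOS) model.

The model is an unsupervised, naive-Bayes-style scorer: for each of the 18
residue types that carry a chi1 and for each of the five features, a
fixed-width histogram is fitted on a reference set and rescaled so its modal
bin has height 1 (the normalized density function, *npdf*).  A residue's
score is

    HBOS = sum_i log(1 / npdf_i(v_i))      (five features)

so a residue whose every feature sits in the most popular bin scores 0, and
rare conformations score high.  A residue with HBOS strictly greater than 10
(the default threshold) is an outlier.

Add-one (Laplace) smoothing keeps every bin positive, so scores are always
finite.  Angle histograms cover [0°, 360°) with 10° bins; distance
histograms cover [0, 10] Å with 0.1 Å bins plus one overflow bin.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .features import ANGLE_FEATURES, FEATURE_NAMES, FeatureRecord

SCHEMA_ID = "hbosprof-model"
SCHEMA_VERSION = 1

DEFAULT_THRESHOLD = 10.0


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class BinningConfig:
    """Histogram geometry and score base.

    angle_bin in degrees over [0, 360); dist_bin in Å over [0, dist_max]
    plus one overflow bin for longer distances; log_base None = natural log.
    """

    angle_bin: float = 10.0
    dist_bin: float = 0.1
    dist_max: float = 10.0
    log_base: float | None = None

    @property
    def n_angle_bins(self) -> int:
        return int(round(360.0 / self.angle_bin))

    @property
    def n_dist_bins(self) -> int:
        # regular bins + 1 overflow
        return int(round(self.dist_max / self.dist_bin)) + 1

    def n_bins(self, feature: str) -> int:
        return self.n_angle_bins if feature in ANGLE_FEATURES else self.n_dist_bins

    def bin_index(self, feature: str, value: float) -> int:
        if feature in ANGLE_FEATURES:
            v = value % 360.0
            return min(int(v / self.angle_bin), self.n_angle_bins - 1)
        if value < 0:
            raise ModelError(f"negative distance {value!r}")
        idx = int(value / self.dist_bin)
        return min(idx, self.n_dist_bins - 1)  # overflow bin collects the tail

    def bin_indices(self, feature: str, values: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`bin_index`."""
        values = np.asarray(values, dtype=float)
        if feature in ANGLE_FEATURES:
            idx = (values % 360.0) / self.angle_bin
            return np.minimum(idx.astype(np.int64), self.n_angle_bins - 1)
        if np.any(values < 0):
            raise ModelError("negative distance value")
        idx = (values / self.dist_bin).astype(np.int64)
        return np.minimum(idx, self.n_dist_bins - 1)

    def log(self, x: float) -> float:
        if self.log_base is None:
            return math.log(x)
        return math.log(x) / math.log(self.log_base)


@dataclass
class FeatureHistogram:
    """Smoothed, max-normalized histogram for one (residue type, feature)."""

    feature: str
    heights: np.ndarray  # npdf per bin, max == 1, all > 0
    n_samples: int

    def lookup(self, config: BinningConfig, value: float) -> float:
        return float(self.heights[config.bin_index(self.feature, value)])


@dataclass
class HistogramModel:
    config: BinningConfig
    histograms: dict[str, dict[str, FeatureHistogram]]  # res_type -> feature -> hist
    description: str = ""
    metadata: dict = field(default_factory=dict)

    @property
    def res_types(self) -> list[str]:
        return sorted(self.histograms)

    def __eq__(self, other) -> bool:
        if not isinstance(other, HistogramModel):
            return NotImplemented
        if self.config != other.config or self.res_types != other.res_types:
            return False
        for rt in self.res_types:
            for feat in FEATURE_NAMES:
                a, b = self.histograms[rt][feat], other.histograms[rt][feat]
                if a.n_samples != b.n_samples or not np.array_equal(a.heights, b.heights):
                    return False
        return True


@dataclass(frozen=True)
class ScoreResult:
    record: FeatureRecord
    feature_scores: tuple[float, ...] | None  # aligned with FEATURE_NAMES
    total: float | None
    unscored: bool
    outlier: bool = False

    @property
    def res_type(self) -> str:
        return self.record.res_type


def fit_model(
    records: Iterable[FeatureRecord],
    config: BinningConfig | None = None,
    description: str = "",
) -> HistogramModel:
    """Fit per-(type, feature) npdf histograms from complete records.

    Records with any unavailable feature are excluded.  Counts get add-one
    smoothing in every bin and are divided by the resulting maximum so the
    modal bin is exactly 1.  Residue types with no complete record are
    omitted with a warning.
    """
    import warnings

    config = config or BinningConfig()
    by_type: dict[str, list[FeatureRecord]] = {}
    n_incomplete = 0
    for rec in records:
        if not rec.complete:
            n_incomplete += 1
            continue
        by_type.setdefault(rec.res_type, []).append(rec)
    if not by_type:
        raise ModelError("no complete feature records to fit on")

    histograms: dict[str, dict[str, FeatureHistogram]] = {}
    for res_type, recs in sorted(by_type.items()):
        per_feature: dict[str, FeatureHistogram] = {}
        values = np.array([rec.values() for rec in recs], dtype=float)
        for i, feature in enumerate(FEATURE_NAMES):
            nb = config.n_bins(feature)
            idx = config.bin_indices(feature, values[:, i])
            counts = np.bincount(idx, minlength=nb).astype(np.int64)
            smoothed = counts + 1
            heights = smoothed / smoothed.max()
            per_feature[feature] = FeatureHistogram(
                feature=feature, heights=heights, n_samples=len(recs)
            )
        histograms[res_type] = per_feature

    model = HistogramModel(
        config=config,
        histograms=histograms,
        description=description,
        metadata={
            "n_records_fit": sum(len(v) for v in by_type.values()),
            "n_records_incomplete": n_incomplete,
            "counts_per_type": {t: len(v) for t, v in sorted(by_type.items())},
        },
    )
    if n_incomplete:
        warnings.warn(f"{n_incomplete} incomplete records excluded from fitting")
    return model


def npdf_lookup(model: HistogramModel, res_type: str, feature: str, value: float) -> float:
    """Smoothed, max-normalized histogram height at *value*, in (0, 1]."""
    try:
        hist = model.histograms[res_type][feature]
    except KeyError:
        raise ModelError(f"model has no histogram for ({res_type!r}, {feature!r})")
    return hist.lookup(model.config, value)


def hbos_score(model: HistogramModel, record: FeatureRecord) -> ScoreResult:
    """Score one residue: sum over features of log(1/npdf)."""
    if not record.complete or record.res_type not in model.histograms:
        return ScoreResult(record=record, feature_scores=None, total=None, unscored=True)
    scores = []
    for feature, value in zip(FEATURE_NAMES, record.values()):
        npdf = npdf_lookup(model, record.res_type, feature, value)
        scores.append(model.config.log(1.0 / npdf))
    return ScoreResult(
        record=record,
        feature_scores=tuple(scores),
        total=float(sum(scores)),
        unscored=False,
    )


def score_records(
    model: HistogramModel,
    records: Iterable[FeatureRecord],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[ScoreResult]:
    return detect_outliers([hbos_score(model, r) for r in records], threshold)


def detect_outliers(
    results: Iterable[ScoreResult], threshold: float = DEFAULT_THRESHOLD
) -> list[ScoreResult]:
    """Flag results with total strictly greater than *threshold*.

    A score of exactly the threshold is not an outlier; unscored records are
    never flagged.
    """
    flagged = []
    for res in results:
        outlier = (not res.unscored) and res.total is not None and res.total > threshold
        flagged.append(
            ScoreResult(
                record=res.record,
                feature_scores=res.feature_scores,
                total=res.total,
                unscored=res.unscored,
                outlier=outlier,
            )
        )
    return flagged


def save_model(model: HistogramModel, path) -> None:
    """Serialize to versioned JSON; floats survive the round trip exactly."""
    payload = {
        "schema": SCHEMA_ID,
        "version": SCHEMA_VERSION,
        "config": {
            "angle_bin": model.config.angle_bin,
            "dist_bin": model.config.dist_bin,
            "dist_max": model.config.dist_max,
            "log_base": model.config.log_base,
        },
        "description": model.description,
        "metadata": model.metadata,
        "histograms": {
            res_type: {
                feat: {
                    "n_samples": hist.n_samples,
                    "heights": hist.heights.tolist(),
                }
                for feat, hist in sorted(per_feature.items())
            }
            for res_type, per_feature in sorted(model.histograms.items())
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_model(path) -> HistogramModel:
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ModelError(f"cannot parse model file {path}: {exc}") from exc
    if payload.get("schema") != SCHEMA_ID or payload.get("version") != SCHEMA_VERSION:
        raise ModelError(
            f"unsupported model schema {payload.get('schema')!r} "
            f"v{payload.get('version')!r}"
        )
    cfg = payload["config"]
    config = BinningConfig(
        angle_bin=cfg["angle_bin"],
        dist_bin=cfg["dist_bin"],
        dist_max=cfg["dist_max"],
        log_base=cfg["log_base"],
    )
    histograms: dict[str, dict[str, FeatureHistogram]] = {}
    for res_type, per_feature in payload["histograms"].items():
        histograms[res_type] = {
            feat: FeatureHistogram(
                feature=feat,
                heights=np.asarray(entry["heights"], dtype=float),
                n_samples=int(entry["n_samples"]),
            )
            for feat, entry in per_feature.items()
        }
    return HistogramModel(
        config=config,
        histograms=histograms,
        description=payload.get("description", ""),
        metadata=payload.get("metadata", {}),
    )


def write_score_tsv(results: Iterable[ScoreResult], path) -> None:
    cols = ["entry", "chain", "seq_id", "icode", "res_type"]
    cols += [f"score_{f}" for f in FEATURE_NAMES]
    cols += ["hbos", "outlier", "unscored"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for res in results:
            r = res.record
            row = [r.entry_id, r.chain_id, str(r.seq_id), r.icode, r.res_type]
            if res.unscored:
                row += ["NA"] * 6 + ["0", "1"]
            else:
                row += [repr(s) for s in res.feature_scores]
                row += [repr(res.total), "1" if res.outlier else "0", "0"]
            fh.write("\t".join(row) + "\n")
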