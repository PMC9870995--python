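"""End-to-end orchestration: cohort -> features -> statistics -> models.

Every output file is stamped with the configuration hash and master seed
so any number in the artifact bundle is reproducible from (inputs, config,
seed) alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import groupstats, rfmodels
from .features import FEATURE_NAMES
from .preprocess import CANONICAL_BANDS
from .synthetic import CohortSpec, PanssModel, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("eegmacro")

SUPPORTED_BANDS = tuple(b.name for b in CANONICAL_BANDS)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Declarative pipeline configuration.

    Either ``features_csv``/``clinical_csv`` point at existing tables, or
    ``simulate`` holds keyword arguments for the synthetic cohort
    generator.  Analysis frequencies are restricted to the four canonical
    bands (nothing above 20 Hz).
    """

    seed: int = 0
    bands: tuple[str, ...] = SUPPORTED_BANDS
    features_csv: str | None = None
    clinical_csv: str | None = None
    simulate: dict | None = None
    ntree: int = 500
    n_subsets: int = 10
    n_perm: int = 1000
    n_folds: int = 10
    outcomes: tuple[str, ...] = rfmodels.PANSS_SUBSCALES

    def validate(self) -> None:
        bad = set(self.bands) - set(SUPPORTED_BANDS)
        if bad:
            raise PipelineError(
                f"unsupported band(s) {sorted(bad)}: analysis is restricted "
                f"to {SUPPORTED_BANDS} (nothing above 20 Hz)")
        if self.simulate is None and (self.features_csv is None
                                      or self.clinical_csv is None):
            raise PipelineError("either simulate parameters or both input "
                                "CSV paths must be given")

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_tables(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    if config.simulate is not None:
        sim = dict(config.simulate)
        sim.setdefault("seed", config.seed)
        coef = sim.pop("panss_coef", None)
        if coef is not None:
            sim["panss_model"] = PanssModel(coef=coef)
        spec = CohortSpec(**sim)
        return generate_cohort(spec)
    features = pd.read_csv(config.features_csv, index_col="subject_id")
    clinical = pd.read_csv(config.clinical_csv)
    missing = set(FEATURE_NAMES) - set(features.columns)
    if missing:
        raise PipelineError(f"feature table lacks columns: {sorted(missing)}")
    return features, clinical


def run_pipeline(config: PipelineConfig, outdir: str) -> dict[str, str]:
    """Run comparison, classification and all regressions; write the bundle.

    Returns a map from artifact name to written path.  Any stage failure
    aborts with the stage name in the raised error.
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.hash(), "seed": config.seed}
    written: dict[str, str] = {}

    def _fail(stage: str, err: Exception) -> PipelineError:
        return PipelineError(f"stage {stage!r} failed: {err}")

    try:
        features, clinical = _load_tables(config)
    except (PipelineError, ValueError, OSError) as err:
        raise _fail("load", err) from err
    if len(features) == 0:
        raise PipelineError("stage 'load' failed: 0 subjects")

    groups = clinical.set_index("subject_id").loc[features.index, "group"]
    feats_only = features[list(FEATURE_NAMES)]

    for name, df in (("features", features.reset_index()),
                     ("clinical", clinical)):
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        written[name] = str(path)

    try:
        comparison = groupstats.compare_cohort(feats_only, groups)
    except Exception as err:
        raise _fail("compare", err) from err
    comparison.to_csv(out / "comparison.csv", index=False)
    written["comparison"] = str(out / "comparison.csv")

    try:
        clf = rfmodels.classify_balanced(
            feats_only, groups.to_numpy(), n_subsets=config.n_subsets,
            ntree=config.ntree, seed=config.seed, n_folds=config.n_folds)
    except Exception as err:
        raise _fail("classify", err) from err
    clf_path = out / "classifier.json"
    clf_path.write_text(json.dumps({**stamp, **clf.summary(),
                                    "accuracy": clf.accuracy,
                                    "sensitivity": clf.sensitivity,
                                    "specificity": clf.specificity}, indent=2))
    written["classifier"] = str(clf_path)

    deltas = rfmodels.delta_panss(clinical)
    patient_feats = feats_only.loc[deltas["subject_id"]]
    for outcome in config.outcomes:
        try:
            rep = rfmodels.rf_regress_permute(
                patient_feats, deltas[f"delta_{outcome}"].to_numpy(),
                outcome_name=outcome, n_perm=config.n_perm,
                ntree=config.ntree, seed=config.seed, n_folds=config.n_folds)
        except Exception as err:
            raise _fail(f"predict:{outcome}", err) from err
        path = out / f"regression_{outcome}.json"
        path.write_text(json.dumps(
            {**stamp, **rep.summary(),
             "vimp": rep.vimp.round(3).to_dict()}, indent=2))
        written[f"regression_{outcome}"] = str(path)

    manifest = out / "manifest.json"
    manifest.write_text(json.dumps({**stamp, "artifacts": written}, indent=2))
    written["manifest"] = str(manifest)
    log.info("pipeline complete: %d artifacts in %s", len(written), outdir)
    return written
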