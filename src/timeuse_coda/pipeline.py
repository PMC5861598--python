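"""End-to-end pipeline: simulate -> QC -> build -> impute -> analyze.

Drives the whole analysis from a single flat configuration, persisting every
intermediate table as plain CSV/JSON and recording a reproducibility
manifest (seeds, per-stage row counts, SHA-256 checksums of every written
artifact).  Stages can be disabled individually; real survey extracts in
the same long diary format can be supplied in place of the simulation
stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .compositions import build_compositions, summarise_exposure
from .inference import (
    adjusted_group_means,
    bootstrap_log_ratio_ci,
    compositional_manova,
    fit_ilr_models,
    interaction_and_stratify,
)
from .qc import apply_qc, select_one_diary_per_participant
from .simulate import CorruptionRates, GeneratorConfig, corrupt_diaries, generate_population
from .taxonomy import DEFAULT_MAPPING, ComponentMapping
from .zeros import impute_augmentation, impute_fixed, zero_pattern_summary

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("timeuse_coda.pipeline")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)


@dataclass
class PipelineConfig:
    """Flat key/value configuration for the full pipeline."""

    out_dir: str = "pipeline_out"
    # simulation (disable and point diaries_csv/participants_csv at real data)
    simulate: bool = True
    n_participants: int = 2000
    seed_generate: int = 1
    seed_corrupt: int = 2
    diaries_csv: str | None = None
    participants_csv: str | None = None
    mapping_yaml: str | None = None
    corrupt: bool = True
    rate_missing_time: float = 0.0005
    rate_few_episodes: float = 0.0005
    rate_missing_basic: float = 0.0004
    rate_ineligible: float = 0.30
    rate_no_sleep: float = 0.001
    # qc
    qc: bool = True
    min_age: float = 16.0
    seed_select: int = 3
    # imputation
    impute: bool = True
    impute_method: str = "augmentation"  # or "fixed"
    detection_limit: float = 10.0
    fixed_value: float = 1.0
    seed_impute: int = 4
    # analysis
    analyze: bool = True
    stage: str = "full"
    n_bootstrap: int = 1000
    seed_bootstrap: int = 5
    modifiers: tuple[str, ...] = ("sex", "work_status", "age_group", "day_type")
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        seeds = {
            "seed_generate": self.seed_generate,
            "seed_corrupt": self.seed_corrupt,
            "seed_select": self.seed_select,
            "seed_impute": self.seed_impute,
            "seed_bootstrap": self.seed_bootstrap,
        }
        for name, s in seeds.items():
            if s is None:
                raise ValueError(f"{name} must be an explicit integer seed")
        if not self.simulate and (self.diaries_csv is None or self.participants_csv is None):
            raise ValueError("either enable simulation or supply diaries_csv and participants_csv")
        if self.impute_method not in ("augmentation", "fixed"):
            raise ValueError("impute_method must be 'augmentation' or 'fixed'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in doc.items() if k in known}
        extra = {k: v for k, v in doc.items() if k not in known}
        if "modifiers" in kwargs:
            kwargs["modifiers"] = tuple(kwargs["modifiers"])
        return cls(**kwargs, extra=extra)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the manifest dict.

    The manifest records the package version, every seed, per-stage row
    counts (diary attrition accounting) and a checksum for each artifact
    written under ``config.out_dir``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mapping = (
        ComponentMapping.load(config.mapping_yaml) if config.mapping_yaml else DEFAULT_MAPPING
    )
    manifest: dict = {
        "package_version": __version__,
        "config": {k: v for k, v in asdict(config).items() if k != "extra"},
        "counts": {},
        "checksums": {},
    }
    artifacts: list[Path] = []

    def persist(name: str, writer) -> None:
        path = out / name
        writer(path)
        artifacts.append(path)

    # --- simulate ---------------------------------------------------------
    if config.simulate:
        log.info("simulating %d participants (seed %d)", config.n_participants, config.seed_generate)
        gen = GeneratorConfig(n_participants=config.n_participants, seed=config.seed_generate)
        participants, diaries, truth = generate_population(gen)
        persist("truth.json", lambda p: p.write_text(json.dumps(truth.to_dict(), indent=2)))
        if config.corrupt:
            rates = CorruptionRates(
                config.rate_missing_time,
                config.rate_few_episodes,
                config.rate_missing_basic,
                config.rate_ineligible,
                config.rate_no_sleep,
            )
            diaries, corruption_log = corrupt_diaries(
                diaries, rates, seed=config.seed_corrupt, mapping=mapping
            )
            persist("corruption_log.csv", lambda p: _write_csv(corruption_log, p))
            manifest["counts"]["corrupted_diaries"] = len(corruption_log)
        persist("participants.csv", lambda p: _write_csv(participants, p))
        persist("diaries.csv", lambda p: _write_csv(diaries, p))
    else:
        log.info("loading diaries from %s", config.diaries_csv)
        diaries = pd.read_csv(config.diaries_csv)
        participants = pd.read_csv(config.participants_csv)
    n_diaries = diaries["diary_id"].nunique()
    manifest["counts"]["diaries_in"] = int(n_diaries)
    manifest["counts"]["participants_in"] = int(participants["participant_id"].nunique())

    # --- qc ---------------------------------------------------------------
    if config.qc:
        diaries, report = apply_qc(diaries, participants, mapping, min_age=config.min_age)
        for line in report.log_lines():
            log.info("%s", line)
        persist("qc_report.json", lambda p: p.write_text(report.to_json()))
        manifest["counts"].update({f"qc_{k}": v for k, v in report.to_dict().items()})
        if manifest["counts"]["qc_n_retained"] != (
            manifest["counts"]["qc_n_input"] - report.n_removed
        ):
            raise RuntimeError("QC accounting does not conserve diary counts")
        diaries = select_one_diary_per_participant(diaries, seed=config.seed_select)
        manifest["counts"]["diaries_selected"] = int(diaries["diary_id"].nunique())

    # --- build ------------------------------------------------------------
    comp = build_compositions(diaries, participants, mapping)
    exposure = summarise_exposure(diaries, mapping)
    persist("compositions.csv", lambda p: _write_csv(comp, p))
    persist(
        "exposure_summary.json",
        lambda p: p.write_text(json.dumps(exposure.to_dict(), indent=2)),
    )
    manifest["counts"]["compositions"] = len(comp)
    zp = zero_pattern_summary(comp)
    persist(
        "zero_patterns.json", lambda p: p.write_text(json.dumps(zp.to_dict(), indent=2))
    )

    # --- impute -----------------------------------------------------------
    if config.impute:
        log.info("imputing %d zero cells (%s)", int(zp.zero_counts.sum()), config.impute_method)
        if config.impute_method == "augmentation":
            imp = impute_augmentation(
                comp, detection_limit=config.detection_limit, seed=config.seed_impute
            )
        else:
            imp = impute_fixed(comp, value=config.fixed_value)
        persist("imputed.csv", lambda p: _write_csv(imp.data, p))
        persist(
            "imputed_flags.csv",
            lambda p: _write_csv(
                pd.DataFrame(imp.imputed, columns=list(zp.zero_counts.index)), p
            ),
        )
        analysis_table = imp.data
    else:
        analysis_table = comp

    # --- analyze ----------------------------------------------------------
    if config.analyze:
        manova = {
            st: compositional_manova(analysis_table, stage=st).to_dict()
            for st in ("unadjusted", "age_sex", "full")
        }
        persist("manova.json", lambda p: p.write_text(json.dumps(manova, indent=2)))
        fit = fit_ilr_models(analysis_table, stage=config.stage)
        means = adjusted_group_means(fit)
        persist("adjusted_means.csv", lambda p: _write_csv(means.to_frame(), p))
        lr = bootstrap_log_ratio_ci(
            analysis_table,
            stage=config.stage,
            B=config.n_bootstrap,
            seed=config.seed_bootstrap,
        )
        persist("logratio_differences.csv", lambda p: _write_csv(lr.table, p))
        strata_dir = out / "strata"
        for modifier in config.modifiers:
            res = interaction_and_stratify(
                analysis_table,
                modifier,
                stage=config.stage,
                B=config.n_bootstrap,
                seed=config.seed_bootstrap,
            )
            manifest["counts"][f"interaction_p_{modifier}"] = res.manova.p_value
            if res.strata:
                strata_dir.mkdir(exist_ok=True)
                for lv, s in res.strata.items():
                    safe = str(lv).replace("/", "_")
                    persist(
                        f"strata/{modifier}_{safe}_adjusted_means.csv",
                        lambda p, s=s: _write_csv(s.means.to_frame(), p),
                    )
                    persist(
                        f"strata/{modifier}_{safe}_logratio.csv",
                        lambda p, s=s: _write_csv(s.log_ratio.table, p),
                    )

    for path in artifacts:
        manifest["checksums"][str(path.relative_to(out))] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("pipeline complete; %d artifacts in %s", len(artifacts), out)
    return manifest
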