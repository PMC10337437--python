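"""Pipeline orchestration and publication-style outputs.

``run_pipeline`` ties the stages together: obtain microdata (generator,
fixture or CSV), compute wealth quintiles, assemble the overall and
per-setting cascades, run the bivariate tables and the undiagnosed-status
regression, and write every artifact plus a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .associations import chi_square_test, crosstab, fisher_test, fit_undiagnosed_model
from .cascade import CascadeResult, build_cascade
from .simulate import (
    FixtureSpec,
    GeneratorParams,
    generate_population,
    load_fixture_spec,
    paper_fixture_spec,
    read_microdata,
    reconstruct_fixture,
    write_microdata,
)
from .types import (
    ANALYSIS_COVARIATES,
    CASCADE_BARS,
    CascadeConfig,
    ConvergenceError,
    DegenerateInputError,
    ParameterError,
    SeparationError,
)

log = logging.getLogger("carecascade")


@dataclass
class PipelineConfig:
    """One data source, one output directory, the knobs in between."""

    input_csv: Optional[str] = None
    generator_yaml: Optional[str] = None
    fixture_yaml: Optional[str] = None   # "paper" selects the packaged fixture
    output_dir: str = "carecascade_out"
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    covariates: list = field(default_factory=lambda: list(ANALYSIS_COVARIATES))
    alpha: float = 0.05
    use_fisher: bool = False
    seed: int = 0

    def validate(self) -> None:
        sources = [s for s in (self.input_csv, self.generator_yaml,
                               self.fixture_yaml) if s]
        if len(sources) != 1:
            raise ParameterError(
                "exactly one data source must be specified "
                "(input_csv, generator_yaml or fixture_yaml)")
        self.cascade.validate()


def _load_generator_params(path, seed) -> GeneratorParams:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    raw.setdefault("seed", seed)
    return GeneratorParams(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def render_cascade_chart_data(results) -> pd.DataFrame:
    """Long-format (stratum, stage, percent) table, chart-ready.

    Rows are ordered bar-first within stratum, overall stratum first, as a
    grouped bar chart of the cascades by setting would display them.
    """
    if isinstance(results, CascadeResult):
        results = [results]
    if not results:
        raise ParameterError("need at least one CascadeResult")
    ordered = sorted(results, key=lambda r: (r.stratum is not None,))
    rows = []
    for res in ordered:
        for stage in CASCADE_BARS:
            rows.append({
                "stratum": res.stratum or "overall",
                "stage": stage,
                "percent": round(res.bar_percent(stage), 1),
            })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary.

    Identical config + seed + input bytes produce byte-identical artifacts
    (and therefore identical manifest checksums).  On error, partial outputs
    are removed and the failure is re-raised with the stage name.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    stage = "load"
    t0 = time.perf_counter()
    try:
        # --- data source
        input_checksum = None
        if config.input_csv:
            input_checksum = _sha256(Path(config.input_csv))
            data = read_microdata(config.input_csv)
            source = f"csv:{config.input_csv}"
        elif config.generator_yaml:
            params = _load_generator_params(config.generator_yaml, config.seed)
            data = generate_population(params)
            source = f"generator:{config.generator_yaml}"
        else:
            if config.fixture_yaml == "paper":
                spec = paper_fixture_spec()
                source = "fixture:paper"
            else:
                input_checksum = _sha256(Path(config.fixture_yaml))
                spec = load_fixture_spec(config.fixture_yaml)
                source = f"fixture:{config.fixture_yaml}"
            data = reconstruct_fixture(spec)
        log.info("loaded %d records from %s", len(data), source)

        stage = "microdata"
        micro_path = out_dir / "microdata.csv"
        write_microdata(data, micro_path)
        written.append(micro_path)

        stage = "wealth"
        from .wealth import attach_wealth_quintile, compute_wealth_index
        from .types import ASSET_COLUMNS
        households = data.drop_duplicates("household_id").set_index("household_id")
        wealth = compute_wealth_index(households[ASSET_COLUMNS], households.index)
        data = attach_wealth_quintile(data)
        path = out_dir / "wealth_index.csv"
        wealth.to_csv(path, index=False, float_format="%.10g")
        written.append(path)
        log.info("wealth index computed for %d households", len(wealth))

        stage = "cascade"
        results = build_cascade(data, config.cascade, stratify_by="setting")
        cascade_frame = pd.concat([r.to_frame() for r in results],
                                  ignore_index=True)
        cascade_frame["percent"] = cascade_frame["percent"].round(1)
        path = out_dir / "cascade.csv"
        cascade_frame.to_csv(path, index=False)
        written.append(path)
        path = out_dir / "cascade.json"
        path.write_text(json.dumps([r.to_dict() for r in results], indent=2),
                        encoding="utf-8")
        written.append(path)
        chart = render_cascade_chart_data(results)
        path = out_dir / "cascade_chart_data.csv"
        chart.to_csv(path, index=False)
        written.append(path)
        overall = results[0]
        degenerate = overall.degenerate
        if degenerate:
            log.warning("no cases found: cascade is all-zero, "
                        "association stages will be skipped")

        stage = "bivariate"
        skipped_reason = None
        if not degenerate:
            tables = []
            for cov in config.covariates:
                tab = crosstab(data, cov, config.cascade)
                frame = tab.to_frame()
                try:
                    if config.use_fisher:
                        p = fisher_test(tab, seed=config.seed)
                    else:
                        _, _, p = chi_square_test(tab)
                except DegenerateInputError:
                    p = float("nan")
                frame["p_value"] = p
                tables.append(frame)
            path = out_dir / "bivariate_tables.csv"
            pd.concat(tables, ignore_index=True).to_csv(
                path, index=False, float_format="%.10g")
            written.append(path)
        else:
            skipped_reason = "no cases in the data"

        stage = "regression"
        if not degenerate:
            try:
                model = fit_undiagnosed_model(
                    data, config.covariates, alpha=config.alpha,
                    config=config.cascade)
                path = out_dir / "undiagnosed_model.csv"
                model.estimates.to_csv(path, index=False,
                                       float_format="%.10g")
                written.append(path)
                path = out_dir / "elimination_trace.json"
                path.write_text(
                    json.dumps(model.elimination_trace, indent=2),
                    encoding="utf-8")
                written.append(path)
            except (DegenerateInputError, SeparationError,
                    ConvergenceError) as exc:
                # margins-only reconstructions and very small samples can
                # separate; the cascade/bivariate outputs stand on their own
                skipped_reason = str(exc)
                log.warning("regression skipped: %s", exc)

        stage = "manifest"
        manifest = {
            "package": "carecascade",
            "version": __version__,
            "seed": config.seed,
            "source": source,
            "input_checksum": input_checksum,
            "n_records": int(len(data)),
            "denominator": overall.denominator,
            "bars": {name: count for name, count, _ in overall.bars},
            "degenerate": degenerate,
            "skipped": skipped_reason,
            "artifacts": {p.name: _sha256(p) for p in written},
        }
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2), encoding="utf-8")
        log.info("pipeline finished in %.2fs", time.perf_counter() - t0)
        return manifest
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        try:
            wrapped = type(exc)(f"pipeline stage '{stage}': {exc}")
        except Exception:
            wrapped = RuntimeError(f"pipeline stage '{stage}': {exc}")
        raise wrapped from exc
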