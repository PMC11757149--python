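"""End-to-end pipeline: simulate -> scan -> windows -> entropy/null ->
compare -> logo -> phenotype, driven by one config with explicit seeds.

Every random stage derives its seed from the config's master seed, so a
rerun with the same config produces byte-identical outputs and an
identical checksum manifest.  A ``RunReport`` (stage statuses, parameter
echo, file manifest with SHA-256 checksums, warnings) is written even
when a stage fails; downstream stages are then skipped and the failure
recorded rather than raised, so a partial run still leaves a parseable
report.  Configuration and dependency problems detected before
execution, by contrast, raise immediately.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .model import FlankConservation
from .motifs import CONSENSUS, find_motif, report_upstream_distance, extract_windows
from .phenotype import (
    motif_phenotype_association,
    relative_expression_table,
    shoulder_index_table,
)
from .simulate import (
    CdsSpec,
    MorphoSpec,
    PanelSpec,
    simulate_cds_alignment,
    simulate_ct,
    simulate_measurements,
    simulate_promoter_panel,
)
from .stats import one_sided_t_test

STAGES = (
    "simulate",
    "scan",
    "windows",
    "entropy",
    "null",
    "compare",
    "logo",
    "phenotype",
)


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


class DependencyError(ConfigError):
    """A stage is enabled but its required input stage/file is missing."""


@dataclass
class RunConfig:
    """One self-contained description of a pipeline run.

    ``stages`` toggles which steps execute; stage seeds are derived from
    ``seed`` deterministically (panel seed, cds seed+1, null seed+2,
    morphometrics seed+3, CT seed+4) unless a sub-spec supplies its own.
    """

    outdir: str = "motifcons_run"
    seed: int = 0
    consensus: str = CONSENSUS
    flank_len: int = 12
    width: int = 6
    step: int = 1
    test_step: int | None = None
    n_null: int = 1000
    null_k: int = 6
    both_strands: bool = False
    upstream_convention: str = "end"
    stages: tuple[str, ...] = STAGES
    panel: dict = field(default_factory=dict)
    cds: dict = field(default_factory=dict)
    morpho: dict = field(default_factory=dict)
    ct: dict = field(default_factory=dict)
    panel_fasta: str | None = None
    cds_fasta: str | None = None
    measurements_tsv: str | None = None
    ct_tsv: str | None = None

    def __post_init__(self) -> None:
        self.stages = tuple(self.stages)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}")
        if self.upstream_convention not in {"end", "start"}:
            raise ConfigError("upstream_convention must be 'end' or 'start'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass
class RunReport:
    stages: list[dict]
    params: dict
    manifest: dict[str, str]
    warnings: list[str]

    def status(self, stage: str) -> str:
        for entry in self.stages:
            if entry["stage"] == stage:
                return entry["status"]
        return "disabled"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _validate_dependencies(config: RunConfig) -> None:
    on = set(config.stages)
    simulate = "simulate" in on
    if {"scan", "windows"} & on and not simulate and not config.panel_fasta:
        raise DependencyError(
            "scan/windows stages need a promoter panel: enable the simulate "
            "stage or supply panel_fasta"
        )
    if "null" in on and not simulate and not config.cds_fasta:
        raise DependencyError(
            "null stage needs a CDS alignment: enable the simulate stage or "
            "supply cds_fasta"
        )
    for stage, needs in (
        ("windows", "scan"),
        ("entropy", "windows"),
        ("compare", "entropy"),
        ("logo", "windows"),
    ):
        if stage in on and needs not in on:
            raise DependencyError(f"{stage} stage requires the {needs} stage")
    if "phenotype" in on and not simulate and not (
        config.measurements_tsv and config.ct_tsv
    ):
        raise DependencyError(
            "phenotype stage needs measurements and CT input: enable the "
            "simulate stage or supply measurements_tsv and ct_tsv"
        )


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages in dependency order.

    Raises :class:`ConfigError`/:class:`DependencyError` for problems
    detectable before execution.  A runtime stage failure is recorded in
    the report, downstream stages are skipped, and the report is still
    written to ``<outdir>/report.json``.
    """
    _validate_dependencies(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    state: dict[str, Any] = {}
    stage_entries: list[dict] = []
    emitted: list[Path] = []
    caught: list[str] = []
    halted = False

    def _emit_table(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        mio.write_table(df, path)
        emitted.append(path)

    def _emit_text(text: str, name: str) -> None:
        path = outdir / name
        path.write_text(text)
        emitted.append(path)

    def _stage_simulate() -> None:
        panel_spec = PanelSpec(**{"seed": config.seed, **config.panel})
        panel = simulate_promoter_panel(panel_spec)
        panel.to_fasta(outdir / "panel.fasta")
        emitted.append(outdir / "panel.fasta")
        _emit_table(panel.truth, "panel_truth.tsv")
        state["panel"] = panel
        state["panel_records"] = list(panel.records)

        cds_spec = CdsSpec(**{"seed": config.seed + 1, **config.cds})
        cds = simulate_cds_alignment(cds_spec)
        cds.to_fasta(outdir / "cds.fasta")
        emitted.append(outdir / "cds.fasta")
        _emit_table(
            pd.DataFrame({"fourfold_column": cds.true_fourfold_columns}),
            "cds_fourfold_truth.tsv",
        )
        state["cds_records"] = list(cds.records)

        morpho_spec = MorphoSpec(**{"seed": config.seed + 3, **config.morpho})
        measurements = simulate_measurements(morpho_spec)
        _emit_table(measurements, "measurements.tsv")
        state["measurements"] = measurements

        ct_kwargs = {"n": 6, "seed": config.seed + 4, **config.ct}
        genotypes = list(morpho_spec.genotypes)
        ct_tables = []
        for gi, genotype in enumerate(genotypes):
            # second and later genotypes express less (higher ΔCT), matching
            # the reduced-expression alleles the phenotype stage contrasts
            kw = dict(ct_kwargs)
            kw["seed"] = ct_kwargs["seed"] + gi
            kw.setdefault("delta_ct_mean", 1.0)
            if gi > 0:
                kw["delta_ct_mean"] = kw["delta_ct_mean"] + 2.0
            tbl = simulate_ct(**kw)
            tbl.insert(1, "genotype", genotype)
            tbl["sample_id"] = [f"{genotype}_{s}" for s in tbl["sample_id"]]
            ct_tables.append(tbl)
        ct = pd.concat(ct_tables, ignore_index=True)
        _emit_table(ct, "ct.tsv")
        state["ct"] = ct
        state["association"] = panel.association_table()
        _emit_table(state["association"], "species_association.tsv")

    def _load_panel() -> list:
        if "panel_records" not in state:
            state["panel_records"] = mio.read_fasta(config.panel_fasta)
        return state["panel_records"]

    def _stage_scan() -> None:
        records = _load_panel()
        rows = []
        for rec in records:
            for hit in find_motif(
                rec, consensus=config.consensus, both_strands=config.both_strands
            ):
                distance = None
                if hit.strand == "+" and hit.end <= len(rec):
                    # promoter FASTA convention: sequence ends just 5' of ATG
                    distance = report_upstream_distance(
                        hit, len(rec), convention=config.upstream_convention
                    )
                rows.append(
                    {
                        "sequence_id": rec.id,
                        "start": hit.start,
                        "end": hit.end,
                        "strand": hit.strand,
                        "matched": hit.matched,
                        "upstream_distance": distance,
                    }
                )
        hits = pd.DataFrame(
            rows,
            columns=[
                "sequence_id", "start", "end", "strand", "matched",
                "upstream_distance",
            ],
        )
        _emit_table(hits, "hits.tsv")
        state["hits"] = hits

    def _stage_windows() -> None:
        records = _load_panel()
        hits = state["hits"]
        counts = hits.groupby("sequence_id").size()
        single = [rid for rid, n in counts.items() if n == 1]
        if not single:
            raise ValueError(
                "no sequence with exactly one consensus hit; cannot choose an "
                "anchor for window extraction"
            )
        order = {rec.id: i for i, rec in enumerate(records)}
        anchor_id = min(single, key=lambda rid: order.get(rid, len(order)))
        anchor_start = int(
            hits.loc[hits["sequence_id"] == anchor_id, "start"].iloc[0]
        )
        state["anchor"] = (anchor_id, anchor_start)
        with20, without20 = extract_windows(
            records, anchor_id, anchor_start,
            consensus=config.consensus, flank=7,
        )
        state["windows20"] = (with20, without20)
        for wset, name in ((with20, "windows_with_site.fasta"),
                           (without20, "windows_without_site.fasta")):
            mio.write_fasta(wset.to_records(), outdir / name)
            emitted.append(outdir / name)

    def _get_results(with_null: bool):
        key = "results_null" if with_null else "results"
        if key not in state:
            anchor_id, anchor_start = state["anchor"]
            cds = state.get("cds_records")
            if with_null and cds is None and config.cds_fasta:
                cds = mio.read_fasta(config.cds_fasta, role="cds")
                state["cds_records"] = cds
            model = FlankConservation.from_panel(
                _load_panel(), anchor_id, anchor_start,
                consensus=config.consensus, flank_len=config.flank_len,
                cds=cds if with_null else None,
                width=config.width, display_step=config.step,
                test_step=config.test_step, n_null=config.n_null,
                null_k=config.null_k,
            )
            state[key] = model.fit(seed=config.seed + 2)
        return state[key]

    def _stage_entropy() -> None:
        results = _get_results(with_null=False)
        _emit_table(results.profile_frame("display"), "profiles.tsv")
        _emit_table(results.profile_frame("test"), "test_profiles.tsv")

    def _stage_null() -> None:
        results = _get_results(with_null=True)
        assert results.null_ is not None
        _emit_table(results.null_.to_frame(), "null_ensemble.tsv")

    def _stage_compare() -> None:
        use_null = "null" in config.stages
        results = _get_results(with_null=use_null)
        payload = {
            name: {
                "U": t.statistic,
                "p_value": t.p_value,
                "n1": t.n1,
                "n2": t.n2,
                "method": t.method,
                "tie_corrected": t.tie_corrected,
                "sidedness": t.sidedness,
            }
            for name, t in results.tests.items()
        }
        payload["samples"] = results.group_summary.to_dict(orient="records")
        payload["conventions"] = {
            "pooling": "window means pooled across both flanks per group",
            "width": config.width,
            "display_step": config.step,
            "test_step": results.model.test_step,
            "flank_len": config.flank_len,
            "upstream_convention": config.upstream_convention,
            "strand": "both" if config.both_strands else "forward",
            "seed": config.seed,
        }
        _emit_text(json.dumps(payload, indent=2, sort_keys=True), "tests.json")
        _emit_text(results.summary() + "\n", "summary.txt")

    def _stage_logo() -> None:
        from .entropy import logo_matrix

        with20, without20 = state["windows20"]
        for wset, name in ((with20, "logo_with_site.tsv"),
                           (without20, "logo_without_site.tsv")):
            _emit_table(logo_matrix(wset).to_frame(), name)

    def _stage_phenotype() -> None:
        measurements = state.get("measurements")
        if measurements is None:
            measurements = mio.read_table(config.measurements_tsv)
        ct = state.get("ct")
        if ct is None:
            ct = mio.read_table(config.ct_tsv)
        shaped = shoulder_index_table(measurements)
        _emit_table(shaped, "shoulder_index.tsv")
        expr = relative_expression_table(ct)
        _emit_table(expr, "expression.tsv")

        payload: dict[str, Any] = {}
        genotypes = list(dict.fromkeys(shaped["genotype"]))
        if len(genotypes) >= 2:
            ref, alt = genotypes[0], genotypes[1]
            shape_test = one_sided_t_test(
                shaped.loc[shaped["genotype"] == ref, "shoulder_index"],
                shaped.loc[shaped["genotype"] == alt, "shoulder_index"],
                direction="greater",
            )
            payload["shoulder_index_t_test"] = {
                "groups": [ref, alt], "t": shape_test.statistic,
                "p_value": shape_test.p_value, "stars": shape_test.stars,
                "direction": shape_test.direction,
            }
            if "genotype" in expr.columns:
                expr_test = one_sided_t_test(
                    expr.loc[expr["genotype"] == ref, "relative_expression"],
                    expr.loc[expr["genotype"] == alt, "relative_expression"],
                    direction="greater",
                )
                payload["expression_t_test"] = {
                    "groups": [ref, alt], "t": expr_test.statistic,
                    "p_value": expr_test.p_value, "stars": expr_test.stars,
                    "direction": expr_test.direction,
                }
        if "association" in state:
            assoc = motif_phenotype_association(state["association"])
            payload["association"] = {
                "counts": np.asarray(assoc.counts).tolist(),
                "concordance": assoc.concordance,
                "fisher_p": assoc.p_value,
            }
        _emit_text(json.dumps(payload, indent=2, sort_keys=True), "phenotype.json")

    runners = {
        "simulate": _stage_simulate,
        "scan": _stage_scan,
        "windows": _stage_windows,
        "entropy": _stage_entropy,
        "null": _stage_null,
        "compare": _stage_compare,
        "logo": _stage_logo,
        "phenotype": _stage_phenotype,
    }

    for stage in STAGES:
        if stage not in config.stages:
            continue
        if halted:
            stage_entries.append(
                {"stage": stage, "status": "skipped",
                 "detail": "upstream stage failed"}
            )
            continue
        try:
            with warnings.catch_warnings(record=True) as caught_here:
                warnings.simplefilter("always")
                runners[stage]()
            caught.extend(f"{stage}: {w.message}" for w in caught_here)
            stage_entries.append({"stage": stage, "status": "ok", "detail": ""})
        except Exception as exc:  # recorded, not raised: report must survive
            stage_entries.append(
                {"stage": stage, "status": "failed", "detail": str(exc)}
            )
            halted = True

    manifest = {
        str(path.relative_to(outdir)): _sha256(path)
        for path in sorted(set(emitted))
        if path.exists()
    }
    report = RunReport(
        stages=stage_entries,
        params=config.to_dict(),
        manifest=manifest,
        warnings=caught,
    )
    (outdir / "report.json").write_text(report.to_json())
    return report
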