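"""End-to-end orchestration: read, validate, count, classify, test, report.

The pipeline composes the library modules over one cohort and writes a
report bundle (TSV tables plus JSON summaries).  Its output equals the
composition of the individually invoked operations on the same inputs, and
re-running with identical inputs is byte-identical apart from the
timestamp line of the run log.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .classification import stratify_dxn, tabulate_dxd
from .cohort import Cohort, read_cohort, validate_cohort
from .fixtures import full_study_cohort
from .frequencies import (
    EmptyStratumError,
    allele_counts,
    carrier_frequency,
    consanguinity_summary,
    genotype_frequency,
)
from .generations import generation_frequencies
from .protparam import MutationSpec, apply_mutation, compare_reports, protparam_report, read_fasta
from .registry import VariantRegistry, default_registry, load_registry
from .stats import chisq_homogeneity

#: The four strata whose GJB2 allele counts feed the homogeneity test.
CHISQ_STRATA = ("dxd-mates", "dxn-affected", "dxn-hearing-partners", "controls")


def bundled_fasta(name: str) -> Path:
    ref = resources.files("dfnb1.data").joinpath(name)
    with resources.as_file(ref) as p:
        return Path(p)


@dataclass
class RunConfig:
    """Inputs and options of one pipeline run.

    ``cohort_path=None`` analyses the bundled reference cohort.  The
    borderline toggle controls whether N62S/E147K count as pathogenic in
    carrier tallies (see :mod:`dfnb1.registry`).
    """

    output_dir: Path
    cohort_path: Path | None = None
    registry_path: Path | None = None
    borderline_pathogenic: bool = False
    cx26_fasta: Path | None = None
    cx30_fasta: Path | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            output_dir=Path(raw["output_dir"]),
            cohort_path=Path(raw["cohort_path"]) if raw.get("cohort_path") else None,
            registry_path=Path(raw["registry_path"]) if raw.get("registry_path") else None,
            borderline_pathogenic=bool(raw.get("borderline_pathogenic", False)),
            cx26_fasta=Path(raw["cx26_fasta"]) if raw.get("cx26_fasta") else None,
            cx30_fasta=Path(raw["cx30_fasta"]) if raw.get("cx30_fasta") else None,
            seed=int(raw.get("seed", 0)),
        )

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: str(v) for k, v in self.__dict__.items()}, sort_keys=True
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # propagate with stage name
                raise PipelineError(name, exc) from exc

        return inner

    return wrap


def _frequency_block(cohort: Cohort) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for stratum in CHISQ_STRATA:
        try:
            all_ft = allele_counts(cohort, stratum, ("GJB2",), "all")
            path_ft = allele_counts(cohort, stratum, ("GJB2",), "pathogenic")
        except EmptyStratumError:
            continue
        out[stratum] = {
            "all": all_ft,
            "pathogenic": path_ft,
            "genotypes": genotype_frequency(cohort, stratum),
        }
    return out


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every analysis stage and write the report bundle.

    Returns the in-memory bundle; any stage error propagates as
    :class:`PipelineError` naming the stage.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Any] = {}

    @_stage("load")
    def load() -> tuple[VariantRegistry, Cohort]:
        if config.registry_path:
            reg = load_registry(config.registry_path)
            if config.borderline_pathogenic:
                reg = reg.with_borderline_pathogenic(True)
        else:
            reg = default_registry(config.borderline_pathogenic)
        if config.cohort_path:
            coh = read_cohort(config.cohort_path, reg)
        else:
            coh = full_study_cohort(reg)
        return reg, coh

    registry, cohort = load()

    @_stage("validate")
    def validate() -> list:
        issues = validate_cohort(cohort)
        if not cohort.individuals:
            raise ValueError("cohort is empty")
        return issues

    bundle["issues"] = validate()

    @_stage("frequencies")
    def freqs() -> dict[str, Any]:
        block = _frequency_block(cohort)
        for stratum, tables in block.items():
            tables["all"].to_dataframe().to_csv(
                outdir / f"alleles_{stratum}.tsv", sep="\t", index=False
            )
            tables["genotypes"].to_csv(
                outdir / f"genotypes_{stratum}.tsv", sep="\t", index=False
            )
        return block

    bundle["frequencies"] = freqs()

    @_stage("carriers")
    def carriers() -> dict[str, Any]:
        out = {}
        for stratum in CHISQ_STRATA:
            try:
                cf = carrier_frequency(cohort, stratum, genes=("GJB2",), basis="alleles")
            except EmptyStratumError:
                continue
            out[stratum] = cf
        return out

    bundle["carriers"] = carriers()

    @_stage("consanguinity")
    def consanguinity() -> dict:
        summary = consanguinity_summary(cohort)
        serial = {
            mt: {k: {"count": t.count, "known": t.known, "percent": t.percent} for k, t in d.items()}
            for mt, d in summary.items()
        }
        (outdir / "consanguinity.json").write_text(json.dumps(serial, indent=2))
        return summary

    bundle["consanguinity"] = consanguinity()

    @_stage("classification")
    def classify() -> dict[str, Any]:
        out: dict[str, Any] = {}
        if cohort.families_of_type("DXD"):
            table = tabulate_dxd(cohort, registry)
            table.to_csv(outdir / "dxd_classification.tsv", sep="\t")
            out["dxd"] = table
        if cohort.families_of_type("DXN"):
            strata = stratify_dxn(cohort, registry)
            serial = {
                k: {
                    "families": s.n_families,
                    "affected_offspring": s.n_with_affected_offspring,
                    "affected_offspring_percent": s.affected_offspring_percent,
                    "mutation_positive": s.n_mutation_positive,
                    "mutation_positive_percent": s.mutation_positive_percent,
                }
                for k, s in strata.items()
            }
            (outdir / "dxn_strata.json").write_text(json.dumps(serial, indent=2))
            out["dxn"] = strata
        return out

    bundle["classification"] = classify()

    @_stage("generations")
    def generations() -> dict[str, Any]:
        out: dict[str, Any] = {}
        for subgroup in ("DXD", "DXN"):
            try:
                out[subgroup] = generation_frequencies(cohort, subgroup, registry)
            except ValueError as exc:
                out[subgroup] = {"not_evaluable": str(exc)}
        serial = {
            k: (v.rounded() if hasattr(v, "rounded") else v) for k, v in out.items()
        }
        (outdir / "generations.json").write_text(json.dumps(serial, indent=2))
        return out

    bundle["generations"] = generations()

    @_stage("chi-square")
    def chisq():
        observed = []
        for stratum in CHISQ_STRATA:
            ft = bundle["frequencies"].get(stratum, {}).get("all")
            if ft is None:
                return None
            observed.append([ft.total_count, ft.denominator - ft.total_count])
        result = chisq_homogeneity(observed)
        (outdir / "chisq.json").write_text(
            json.dumps(
                {
                    "observed": result.observed.tolist(),
                    "expected": result.expected.round(2).tolist(),
                    "statistic": round(result.statistic, 2),
                    "df": result.df,
                    "p_value": result.p_value,
                    "p_band": result.p_band,
                    "correction": result.correction,
                },
                indent=2,
            )
        )
        return result

    bundle["chisq"] = chisq()

    @_stage("protein")
    def protein() -> dict[str, Any]:
        cx26 = read_fasta(config.cx26_fasta or bundled_fasta("cx26_P29033.fasta"))
        cx30 = read_fasta(config.cx30_fasta or bundled_fasta("cx30_synthetic.fasta"))
        native26 = protparam_report(cx26)
        native30 = protparam_report(cx30)
        out: dict[str, Any] = {
            "cx26_native": native26,
            "cx30_native": native30,
            "deltas": {},
        }
        for seq, native, label in (
            (cx26, native26, "p.E42D"),
            (cx30, native30, "p.Q57R"),
            (cx30, native30, "p.E101Q"),
            (cx30, native30, "p.R104H"),
        ):
            mutant = protparam_report(apply_mutation(seq, MutationSpec.parse(label)))
            out["deltas"][label] = compare_reports(native, mutant)
        serial = {
            "cx26_native": native26.as_dict(),
            "cx30_native": native30.as_dict(),
            "deltas": out["deltas"],
        }
        (outdir / "protein_reports.json").write_text(json.dumps(serial, indent=2, default=str))
        return out

    bundle["protein"] = protein()

    @_stage("report")
    def report() -> None:
        log = [
            f"dfnb1 version {__version__}",
            f"config hash {config.config_hash()}",
            f"seed {config.seed}",
            f"individuals {len(cohort.individuals)}, families {len(cohort.families)}",
            f"finished {time.strftime('%Y-%m-%dT%H:%M:%S')}",
        ]
        (outdir / "run_log.txt").write_text("\n".join(log) + "\n")

    report()
    return bundle
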