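"""CSV readers/writers, run configuration and the analysis pipeline.

Profiles travel as CSV/TSV in two dialects:

* *long* — one row per (sample, FA): columns ``sample_id, tissue,
  age_months, basis, fa_label, amount``;
* *wide* — one row per sample: ``sample_id, tissue, age_months, basis``
  plus one column per FA label.

``trace`` is accepted (case-insensitively) as an amount literal and is
round-tripped; FA labels may use any accepted dialect (en-dashes
included) and are canonicalized on read.

A :class:`RunConfig` captures every knob of a run (scheme, alpha, basis,
seed, paths) and round-trips losslessly through YAML; every pipeline
output carries the config hash and seed so a rerun with the same config
is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .groupstats import compare_groups
from .indexes import aggregate_indexes, compute_indexes
from .mowing import compare_mowing
from .nomenclature import ClassificationScheme
from .profiles import Basis, FAProfile, ProfileError, quantify, PeakTable
from .synthetic import default_templates, generate_cohort

__all__ = [
    "ValidationError",
    "RunConfig",
    "read_profiles",
    "write_profiles",
    "read_peak_tables",
    "run_pipeline",
]

_META_COLS = ("sample_id", "tissue", "age_months", "basis")
_TRACE = "trace"


class ValidationError(ValueError):
    """Malformed input table."""


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def _parse_amount(raw, trace_literal: str) -> tuple[float, bool]:
    if isinstance(raw, str) and raw.strip().lower() == trace_literal:
        return 0.0, True
    value = float(raw)
    return value, False


def read_profiles(
    path: str | Path,
    dialect: str = "auto",
    *,
    trace_literal: str = _TRACE,
) -> list[FAProfile]:
    """Read profiles from a long or wide CSV/TSV file.

    ``dialect="auto"`` sniffs: a ``fa_label`` column means long form.
    Raises :class:`ValidationError` listing offenders for unknown basis
    values, negative amounts or duplicate (sample, FA) pairs.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=_sep_for(path), dtype=str)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: empty file") from None
    if frame.empty:
        raise ValidationError(f"{path}: no data rows")
    frame.columns = [c.strip() for c in frame.columns]
    if dialect == "auto":
        dialect = "long" if "fa_label" in frame.columns else "wide"
    if dialect not in ("long", "wide"):
        raise ValueError(f"unknown dialect {dialect!r}")
    required = {"sample_id", "basis"} | ({"fa_label", "amount"} if dialect == "long" else set())
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")

    profiles: list[FAProfile] = []
    for sample_id, chunk in frame.groupby("sample_id", sort=False):
        bases = set(chunk["basis"])
        if len(bases) != 1:
            raise ValidationError(f"{path}: sample {sample_id!r} mixes bases {sorted(bases)}")
        try:
            basis = Basis(bases.pop())
        except ValueError as exc:
            raise ValidationError(f"{path}: sample {sample_id!r}: {exc}") from None
        tissue = chunk["tissue"].iloc[0] if "tissue" in chunk else None
        age_raw = chunk["age_months"].iloc[0] if "age_months" in chunk else None
        age = int(float(age_raw)) if age_raw not in (None, "") and not pd.isna(age_raw) else None

        values: dict[str, float] = {}
        traces: set[str] = set()
        if dialect == "long":
            dup = chunk["fa_label"].duplicated()
            if dup.any():
                offenders = sorted(set(chunk.loc[dup, "fa_label"]))
                raise ValidationError(
                    f"{path}: duplicate (sample, FA) rows for {sample_id!r}: {offenders}"
                )
            items = zip(chunk["fa_label"], chunk["amount"])
        else:
            if len(chunk) != 1:
                raise ValidationError(f"{path}: duplicate wide rows for sample {sample_id!r}")
            fa_cols = [c for c in frame.columns if c not in _META_COLS]
            items = ((c, chunk[c].iloc[0]) for c in fa_cols)
        negative = []
        for label, raw in items:
            if pd.isna(raw):
                continue
            amount, is_trace = _parse_amount(raw, trace_literal)
            if amount < 0:
                negative.append(label)
            values[label] = amount
            if is_trace:
                traces.add(label)
        if negative:
            raise ValidationError(
                f"{path}: negative amounts for sample {sample_id!r}: {sorted(negative)}"
            )
        try:
            profiles.append(
                FAProfile(
                    sample_id=str(sample_id),
                    basis=basis,
                    values=values,
                    tissue=None if tissue is None or pd.isna(tissue) else str(tissue),
                    age_months=age,
                    traces=frozenset(traces),
                )
            )
        except ProfileError as exc:
            raise ValidationError(f"{path}: sample {sample_id!r}: {exc}") from None
    return profiles


def write_profiles(
    profiles: list[FAProfile],
    path: str | Path,
    dialect: str = "long",
    *,
    decimals: int | None = None,
    trace_literal: str = _TRACE,
) -> None:
    """Write profiles to CSV/TSV; trace entries keep their literal."""
    path = Path(path)

    def fmt(p: FAProfile, label: str):
        v = p.values[label]
        if label in p.traces:
            return trace_literal
        return round(v, decimals) if decimals is not None else v

    if dialect == "long":
        rows = [
            {
                "sample_id": p.sample_id,
                "tissue": p.tissue,
                "age_months": p.age_months,
                "basis": p.basis.value,
                "fa_label": label,
                "amount": fmt(p, label),
            }
            for p in profiles
            for label in p.values
        ]
        frame = pd.DataFrame(rows)
    elif dialect == "wide":
        labels = sorted({label for p in profiles for label in p.values})
        rows = []
        for p in profiles:
            row: dict[str, object] = {
                "sample_id": p.sample_id,
                "tissue": p.tissue,
                "age_months": p.age_months,
                "basis": p.basis.value,
            }
            row.update({label: fmt(p, label) for label in labels if label in p.values})
            rows.append(row)
        frame = pd.DataFrame(rows, columns=list(_META_COLS) + labels)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    frame.to_csv(path, sep=_sep_for(path), index=False)


def read_peak_tables(path: str | Path) -> list[PeakTable]:
    """Read a long peak-area CSV: sample_id, fa_label, area plus per-sample
    istd_area, istd_mass_mg, sample_mass_g, basis columns."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path))
    required = {"sample_id", "fa_label", "area", "istd_area", "istd_mass_mg", "sample_mass_g"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    tables = []
    for sample_id, chunk in frame.groupby("sample_id", sort=False):
        basis = Basis(chunk["basis"].iloc[0]) if "basis" in chunk else Basis.MG_PER_G_DW
        tables.append(
            PeakTable(
                areas=dict(zip(chunk["fa_label"], chunk["area"].astype(float))),
                istd_area=float(chunk["istd_area"].iloc[0]),
                istd_mass_mg=float(chunk["istd_mass_mg"].iloc[0]),
                sample_mass_g=float(chunk["sample_mass_g"].iloc[0]),
                sample_basis=basis,
                sample_id=str(sample_id),
                tissue=str(chunk["tissue"].iloc[0]) if "tissue" in chunk else None,
            )
        )
    return tables


# -- configuration ----------------------------------------------------------


@dataclass
class RunConfig:
    """Everything that determines a pipeline run; YAML round-trippable."""

    mode: str = "indexes"  # indexes | mowing | simulate
    alpha: float = 0.05
    welch: bool = True
    seed: int = 0
    trace_literal: str = _TRACE
    index_basis: str = "percent"
    bfa_in_sfa: bool = True
    cla_in_pufa: bool = True
    cla_in_n6: bool = False
    inputs: list[str] = field(default_factory=list)
    output_dir: str = "nutrifa_out"
    simulate_tissue: str = "muscle"
    simulate_n: int = 5
    percent_decimals: int = 1

    def scheme(self) -> ClassificationScheme:
        return ClassificationScheme(
            bfa_in_sfa=self.bfa_in_sfa,
            cla_in_pufa=self.cla_in_pufa,
            cla_in_n6=self.cla_in_n6,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# -- pipeline ---------------------------------------------------------------


def _stage(name: str):
    """Re-raise stage failures with the stage name attached."""

    class _ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            return False

    return _ctx()


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the configured analysis and write its report bundle.

    Modes
    -----
    ``indexes``
        Read profile CSVs, compute per-sample dietary indexes, aggregate
        per tissue, and attach significance letters from the group-stats
        chain run on each index across tissues.
    ``mowing``
        Read two cohorts (before, after); emit the contrast table.
    ``simulate``
        Generate a synthetic cohort from a shipped template.

    Every bundle contains a machine-readable ``run_log.json`` (config,
    config hash, seed, package version) and rounds percentages to
    ``config.percent_decimals`` in the human-readable tables while also
    writing a full-precision companion.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    scheme = config.scheme()

    if config.mode == "indexes":
        with _stage("read"):
            profiles = [p for path in config.inputs for p in read_profiles(path)]
            if not profiles:
                raise ValidationError("no profiles read")
        with _stage("indexes"):
            per_sample = []
            for p in profiles:
                d = compute_indexes(p, scheme)
                row = {"sample_id": p.sample_id, "tissue": p.tissue, **d.as_dict()}
                row["undefined_reasons"] = ";".join(
                    f"{k}={v}" for k, v in sorted(d.reasons.items())
                )
                per_sample.append((p.tissue, d, row))
            frame = pd.DataFrame([r for _, _, r in per_sample])
        with _stage("aggregate"):
            tissues = sorted({t for t, _, _ in per_sample if t is not None})
            agg_rows = []
            for tissue in tissues or [None]:
                cohort = [d for t, d, _ in per_sample if t == tissue]
                agg = aggregate_indexes(cohort)
                agg.insert(0, "tissue", tissue)
                agg_rows.append(agg.reset_index(names="index"))
            aggregated = pd.concat(agg_rows, ignore_index=True)
        with _stage("letters"):
            letters = {}
            for index_name in ("IA", "IT", "HH", "HPI", "n6n3", "pufa_sfa"):
                groups = {
                    t: [
                        getattr(d, index_name)
                        for tt, d, _ in per_sample
                        if tt == t and getattr(d, index_name) is not None
                    ]
                    for t in tissues
                }
                groups = {t: v for t, v in groups.items() if len(v) >= 3}
                if len(groups) >= 2:
                    try:
                        letters[index_name] = compare_groups(groups, config.alpha).letters
                    except ValueError:
                        letters[index_name] = {}
            aggregated["letters"] = [
                letters.get(r["index"], {}).get(r["tissue"], "") for _, r in aggregated.iterrows()
            ]
        written["per_sample"] = out / "indexes_per_sample.csv"
        frame.to_csv(written["per_sample"], index=False)
        written["aggregated"] = out / "indexes_aggregated.csv"
        aggregated.round(6).to_csv(written["aggregated"], index=False)

    elif config.mode == "mowing":
        if len(config.inputs) != 2:
            raise ValidationError("mowing mode needs exactly two inputs: before, after")
        with _stage("read"):
            before = read_profiles(config.inputs[0])
            after = read_profiles(config.inputs[1])
        with _stage("mowing"):
            b_pct = [p for p in before if p.basis is Basis.PERCENT]
            a_pct = [p for p in after if p.basis is Basis.PERCENT]
            b_mg = [p for p in before if p.basis is Basis.MG_PER_G_DW] or None
            a_mg = [p for p in after if p.basis is Basis.MG_PER_G_DW] or None
            result = compare_mowing(
                b_pct, a_pct, b_mg, a_mg, alpha=config.alpha, welch=config.welch, scheme=scheme
            )
        written["mowing_full"] = out / "mowing_contrast_full.csv"
        result.table.to_csv(written["mowing_full"], index_label="label")
        written["mowing"] = out / "mowing_contrast.csv"
        result.table.round(config.percent_decimals).to_csv(written["mowing"], index_label="label")

    elif config.mode == "simulate":
        with _stage("simulate"):
            templates = default_templates()
            if config.simulate_tissue not in templates:
                raise ValidationError(
                    f"unknown tissue {config.simulate_tissue!r}; "
                    f"choose from {sorted(templates)}"
                )
            cohort = generate_cohort(
                templates[config.simulate_tissue], config.simulate_n, config.seed
            )
        written["profiles"] = out / f"simulated_{config.simulate_tissue}.csv"
        write_profiles(cohort, written["profiles"], dialect="long")

    else:
        raise ValidationError(f"unknown pipeline mode {config.mode!r}")

    log = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "nutrifa_version": __version__,
        "outputs": {k: str(v) for k, v in written.items()},
    }
    log_path = out / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True))
    written["log"] = log_path
    return written
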