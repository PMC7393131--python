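"""Schema-validated table I/O and the pipeline orchestrator.

All inputs and outputs are plain CSV/TSV in long format with declared
schemas and explicit keys; wide matrices exist only in memory. Missing
values are written as empty fields; "NA" is accepted on read but never
written. ``run_pipeline`` chains QC -> normalization -> z-scoring ->
regulation calls -> pathway scores -> sensitivity correlation -> FDR and
writes a manifest (full config, input checksums, package version) that
suffices to re-run the analysis.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .errors import (
    IntegrityError,
    ParseError,
    PipelineError,
    SchemaError,
)
from .msprep import MetabolitePanel, normalize_samples, qc_filter
from .pathway_corr import (
    ResistanceScore,
    correlate_pathways,
    pathway_scores,
    regulation_calls,
    z_transform,
)
from .radioresponse import dmid as compute_dmid
from .radioresponse import fit_curve

__all__ = ["TableSchema", "LongTable", "SCHEMAS", "read_long_table",
           "write_table", "run_pipeline"]

NA_SENTINELS = {"", "NA", "NaN", "nan"}


@dataclass(frozen=True)
class TableSchema:
    name: str
    required: tuple
    numeric: tuple = ()
    key: tuple = ()
    #: Groups of alternative columns: at least one of each group must exist.
    one_of: tuple = ()


SCHEMAS = {
    s.name: s
    for s in [
        TableSchema("metabolite_panel",
                    required=("metabolite", "sample", "cell_line", "condition",
                              "replicate", "area"),
                    numeric=("replicate", "area"),
                    key=("metabolite", "sample")),
        TableSchema("pathway_map",
                    required=("metabolite", "pathway"),
                    key=("metabolite",)),
        TableSchema("clonogenic",
                    required=("cell_line", "treatment", "dose_gy",
                              "cells_plated", "colonies", "replicate"),
                    numeric=("dose_gy", "cells_plated", "colonies", "replicate"),
                    key=("cell_line", "treatment", "dose_gy", "replicate")),
        TableSchema("viability",
                    required=("cell_line", "treatment", "dose_gy", "viability",
                              "replicate"),
                    numeric=("dose_gy", "viability", "replicate"),
                    key=("cell_line", "treatment", "dose_gy", "replicate")),
        TableSchema("growth",
                    required=("animal", "arm", "day"),
                    numeric=("day", "volume_mm3", "flux"),
                    key=("animal", "day"),
                    one_of=(("volume_mm3", "flux"),)),
        TableSchema("survival",
                    required=("subject", "group", "time_days", "event"),
                    numeric=("time_days", "event"),
                    key=("subject",)),
        TableSchema("expression_survival",
                    required=("patient", "gene", "expression", "os_days",
                              "os_event"),
                    numeric=("expression", "os_days", "os_event"),
                    key=("patient", "gene")),
        TableSchema("resistance",
                    required=("cell_line", "dmid"),
                    numeric=("dmid",),
                    key=("cell_line",)),
        TableSchema("isotopologue",
                    required=("metabolite", "isotopologue_index", "area"),
                    numeric=("isotopologue_index", "area"),
                    key=("metabolite", "isotopologue_index")),
        # Outputs
        TableSchema("qc_report",
                    required=("metabolite", "cell_line", "condition", "action",
                              "reason"),
                    numeric=("mean", "cv")),
        TableSchema("pathway_scores",
                    required=("pathway", "cell_line", "down_score", "up_score",
                              "n_measured"),
                    numeric=("down_score", "up_score", "n_measured"),
                    key=("pathway", "cell_line")),
        TableSchema("pathway_correlations",
                    required=("pathway", "direction", "n", "r", "p", "q",
                              "significant"),
                    numeric=("n", "r", "p", "q"),
                    key=("pathway", "direction")),
        TableSchema("lq_fits",
                    required=("cell_line", "treatment", "alpha", "beta", "dmid"),
                    numeric=("alpha", "beta", "dmid"),
                    key=("cell_line", "treatment")),
    ]
}


@dataclass
class LongTable:
    """A validated long-format table bound to a named schema."""

    data: pd.DataFrame
    schema_name: str
    source: str = "in-memory"

    @property
    def schema(self) -> TableSchema:
        return SCHEMAS[self.schema_name]

    def equals(self, other: "LongTable", rtol: float = 1e-5) -> bool:
        """Equality up to the 6-significant-digit float serialization."""
        if self.schema_name != other.schema_name:
            return False
        a, b = self.data, other.data
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for col in a.columns:
            if col in self.schema.numeric:
                x = pd.to_numeric(a[col]).to_numpy(dtype=float)
                y = pd.to_numeric(b[col]).to_numpy(dtype=float)
                both_nan = np.isnan(x) & np.isnan(y)
                close = np.isclose(x, y, rtol=rtol, equal_nan=False)
                if not np.all(both_nan | close):
                    return False
            else:
                xa = a[col].astype(object).where(a[col].notna(), None)
                xb = b[col].astype(object).where(b[col].notna(), None)
                if not (xa.to_numpy() == xb.to_numpy()).all():
                    return False
        return True


def _validate(df: pd.DataFrame, schema: TableSchema, source: str) -> pd.DataFrame:
    missing = [c for c in schema.required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{source}: missing required column(s) {missing} "
            f"for schema {schema.name!r}")
    for group in schema.one_of:
        if not any(c in df.columns for c in group):
            raise SchemaError(
                f"{source}: needs at least one of columns {list(group)}")
    for col in schema.numeric:
        if col not in df.columns:
            continue
        raw = df[col]
        converted = pd.to_numeric(raw, errors="coerce")
        bad = converted.isna() & raw.notna() & ~raw.astype(str).isin(NA_SENTINELS)
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ParseError(
                f"{source}: unparseable numeric value {raw.iloc[row]!r} "
                f"in column {col!r}, row {row}")
        df[col] = converted
        if converted.notna().any() and not np.all(
                np.isfinite(converted.dropna())):
            raise ParseError(f"{source}: non-finite value in column {col!r}")
    if schema.key:
        dup = df.duplicated(subset=list(schema.key))
        if dup.any():
            row = int(np.nonzero(dup.to_numpy())[0][0])
            raise IntegrityError(
                f"{source}: duplicate key {tuple(df.loc[df.index[row], list(schema.key)])} "
                f"on {schema.key} (row {row})")
    return df


def read_long_table(path, schema_name: str, sep: str | None = None) -> LongTable:
    """Read and validate a CSV/TSV file against a named schema.

    The delimiter is sniffed unless declared. Empty fields and the "NA"
    sentinel read as missing.
    """
    if schema_name not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema_name!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise SchemaError(f"{path}: empty file")
    if sep is None:
        header = path.open().readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, na_values=list(NA_SENTINELS),
                     keep_default_na=False, dtype=object)
    if df.empty and df.columns.size == 0:
        raise SchemaError(f"{path}: no columns found")
    df = _validate(df, SCHEMAS[schema_name], str(path))
    return LongTable(data=df.reset_index(drop=True), schema_name=schema_name,
                     source=str(path))


def _format_value(v, numeric: bool) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v):
        return ""
    if numeric:
        f = float(v)
        if f == int(f) and abs(f) < 1e15:
            return str(int(f))
        return f"{f:.6g}"
    return str(v)


def write_table(table: LongTable | pd.DataFrame, path,
                schema_name: str | None = None) -> None:
    """Write a table as TSV: integers bit-exact, floats at 6 significant
    digits, missing values as empty fields."""
    if isinstance(table, pd.DataFrame):
        if schema_name is None:
            raise SchemaError("schema_name required when writing a DataFrame")
        table = LongTable(table, schema_name)
    numeric = set(table.schema.numeric)
    df = table.data
    path = Path(path)
    try:
        with path.open("w") as fh:
            fh.write("\t".join(map(str, df.columns)) + "\n")
            for row in df.itertuples(index=False):
                fh.write("\t".join(
                    _format_value(v, c in numeric)
                    for c, v in zip(df.columns, row)) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write table to {path}: {exc}") from exc


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _panel_from_table(table: LongTable) -> MetabolitePanel:
    return MetabolitePanel(table.data.copy())


def _resistance_from_inputs(inputs: dict, config: RunConfig,
                            out_dir: Path, written: list) -> ResistanceScore:
    if "resistance" in inputs:
        table = read_long_table(inputs["resistance"], "resistance")
        series = table.data.set_index("cell_line")["dmid"].astype(float)
        return ResistanceScore(series)
    if "clonogenic" in inputs:
        table = read_long_table(inputs["clonogenic"], "clonogenic")
        fits = []
        for (line, treatment), sub in table.data.groupby(["cell_line",
                                                          "treatment"]):
            curve = fit_curve(sub)
            fits.append({"cell_line": line, "treatment": treatment,
                         "alpha": curve.alpha, "beta": curve.beta,
                         "dmid": compute_dmid(curve, config.dose_max,
                                              method=config.dmid_method)})
        fit_df = pd.DataFrame(fits)
        out = out_dir / "lq_fits.tsv"
        write_table(fit_df, out, schema_name="lq_fits")
        written.append(out)
        control = fit_df[fit_df["treatment"] == "control"]
        if control.empty:
            control = fit_df
        return ResistanceScore(control.set_index("cell_line")["dmid"])
    raise PipelineError("stage resistance: provide a 'resistance' or "
                        "'clonogenic' input role")


def run_pipeline(config: RunConfig, inputs: dict, out_dir) -> dict:
    """Execute qc -> scoring -> correlation -> FDR and write all outputs.

    ``inputs`` maps roles to paths: metabolite_panel and pathway_map are
    required; resistance (cell_line, dmid) or clonogenic supplies the
    radioresistance score. Outputs (TSV + manifest.json) land in
    ``out_dir``; any stage error removes partial outputs and aborts with
    the stage name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for role in ("metabolite_panel", "pathway_map"):
        if role not in inputs:
            raise PipelineError(f"stage inputs: missing required role {role!r}")
        if not Path(inputs[role]).exists():
            raise PipelineError(
                f"stage inputs: input {role!r} not found at {inputs[role]}")
    written: list = []
    stage = "inputs"
    try:
        panel = _panel_from_table(
            read_long_table(inputs["metabolite_panel"], "metabolite_panel"))
        pathway_map = read_long_table(inputs["pathway_map"], "pathway_map").data

        stage = "resistance"
        resistance = _resistance_from_inputs(inputs, config, out_dir, written)

        stage = "qc"
        panel, qc_report = qc_filter(panel, config.min_ion_area, config.max_cv,
                                     config.max_missing_frac)
        panel, factors = normalize_samples(panel, config.normalization)
        qc_path = out_dir / "qc_report.tsv"
        write_table(qc_report, qc_path, schema_name="qc_report")
        written.append(qc_path)
        filtered_path = out_dir / "filtered_panel.tsv"
        write_table(panel.data.sort_values(["metabolite", "sample"])
                    .reset_index(drop=True),
                    filtered_path, schema_name="metabolite_panel")
        written.append(filtered_path)

        stage = "scoring"
        if config.unit_of_analysis == "cell_line_mean":
            matrix = panel.line_means()
            unit_resistance = resistance
        else:
            matrix = panel.data.pivot_table(index="metabolite",
                                            columns="sample", values="area")
            line_of = panel.data.drop_duplicates("sample").set_index(
                "sample")["cell_line"]
            unit_resistance = ResistanceScore(
                line_of.map(resistance.dmid).reindex(matrix.columns))
        zmat = z_transform(matrix)
        calls = regulation_calls(zmat, config.z_lower, config.z_upper)
        scores = pathway_scores(calls, pathway_map)
        score_rows = (
            scores.down.stack().rename("down_score").to_frame()
            .join(scores.up.stack().rename("up_score"))
            .join(scores.n_measured.stack().rename("n_measured"))
            .reset_index()
        )
        score_rows.columns = ["pathway", "cell_line", "down_score",
                              "up_score", "n_measured"]
        scores_path = out_dir / "pathway_scores.tsv"
        write_table(score_rows.sort_values(["pathway", "cell_line"])
                    .reset_index(drop=True),
                    scores_path, schema_name="pathway_scores")
        written.append(scores_path)

        stage = "correlation"
        corr = pd.concat(
            [correlate_pathways(scores, unit_resistance, direction=d,
                                fdr_threshold=config.fdr_threshold,
                                p_threshold=config.p_threshold)
             for d in ("down", "up")],
            ignore_index=True,
        ).sort_values(["direction", "pathway"]).reset_index(drop=True)
        corr_path = out_dir / "pathway_correlations.tsv"
        write_table(corr, corr_path, schema_name="pathway_correlations")
        written.append(corr_path)
        ipath = corr[corr["significant"]][["pathway", "r"]]
        ipath_path = out_dir / "ipath_export.tsv"
        with ipath_path.open("w") as fh:
            fh.write("pathway\tscore\n")
            for row in ipath.itertuples(index=False):
                fh.write(f"{row.pathway}\t{row.r:.6g}\n")
        written.append(ipath_path)

        stage = "manifest"
        manifest = {
            "package": "radiometab",
            "version": __version__,
            "config": config.to_dict(),
            "inputs": {role: {"path": str(p), "sha256": _sha256(p)}
                       for role, p in inputs.items()},
            "outputs": sorted(p.name for p in written) + ["manifest.json"],
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True)
                                 + "\n")
        written.append(manifest_path)
    except Exception as exc:
        for p in written:
            Path(p).unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage}: {exc}") from exc
    return {p.stem: str(p) for p in written}
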