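"""File formats, run configuration and unit presentation.

Internal unit is kJ/mol everywhere; kilocalories appear only at
presentation boundaries.  Work values travel either as scalar work files
(one value per line, ``#`` comments) or as two-column lambda / dH-dlambda
tables in an xvg-style dialect (``#`` and ``@`` lines ignored) that are
integrated on read.  Which file belongs to which transformation leg is
stated explicitly in a sidecar manifest CSV rather than encoded in file
names.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._constants import (
    ASSAY_TEMPERATURE,
    KJ_PER_KCAL,
    KJ_PER_KCAL_IT,
    SIM_TEMPERATURE,
    Z_95,
)
from .affinity import InhibitionRecord
from .exceptions import FormatError, InsufficientDataError, InvalidParameterError
from .workset import WorkSet, integrate_work

__all__ = [
    "RunConfig",
    "convert_units",
    "read_work_file",
    "write_work_file",
    "write_dhdl_file",
    "read_inhibition_csv",
    "write_inhibition_csv",
    "load_cdk_inhibition",
    "read_work_directory",
    "write_worksets",
]

MANIFEST_COLUMNS = ["path", "compound_i", "compound_j", "target", "leg", "conformer", "direction"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration shared across pipeline stages.

    ``temperature_K`` governs the experimental IC50 -> ddG conversion
    (default: the 30 degree C assay temperature); ``sim_temperature_K``
    is the default for simulated work distributions.  ``seed`` is required
    by any stochastic step (synthetic sampling, bootstrap).
    """

    temperature_K: float = ASSAY_TEMPERATURE
    sim_temperature_K: float = SIM_TEMPERATURE
    n_boot: int = 1000
    seed: int = 0
    reference_compound: str = "1"
    reference_target: str = "CDK2"
    selectivity_compound: str = "2"
    methods: tuple[str, ...] = ("JAR", "CGI", "BAR")
    z_95: float = field(default=Z_95, init=False)
    kcal_kJ: float = field(default=KJ_PER_KCAL, init=False)

    def __post_init__(self) -> None:
        if self.temperature_K <= 0 or self.sim_temperature_K <= 0:
            raise InvalidParameterError("temperatures must be positive")
        if self.n_boot < 2:
            raise InvalidParameterError("n_boot must be >= 2")


def convert_units(value_kJmol: float, convention: str = "thermochemical") -> float:
    """kJ/mol -> kcal/mol.

    ``convention="thermochemical"`` divides by 4.184 (so 3.5 kJ/mol gives
    0.8365, printing as 0.84 at two decimals); ``"IT"`` divides by 4.1868
    (0.8360).  Published equivalents such as "3.5 kJ/mol = 0.83 kcal/mol"
    arise from truncating the raw quotient rather than rounding; both
    conventions are exposed and the raw quotient is returned untouched.
    """
    if not np.isfinite(value_kJmol):
        raise InvalidParameterError("value must be finite")
    if convention == "thermochemical":
        return value_kJmol / KJ_PER_KCAL
    if convention == "IT":
        return value_kJmol / KJ_PER_KCAL_IT
    raise InvalidParameterError(f"unknown calorie convention {convention!r}")


def _parse_columns(path: Path, n_cols: int, skip_prefixes: tuple[str, ...]):
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(skip_prefixes):
                continue
            parts = line.split()
            if len(parts) != n_cols:
                raise FormatError(
                    f"{path}:{lineno}: expected {n_cols} column(s), got "
                    f"{len(parts)}: {line!r}"
                )
            try:
                values = [float(p) for p in parts]
            except ValueError:
                raise FormatError(f"{path}:{lineno}: unparseable number in {line!r}") from None
            if not all(np.isfinite(values)):
                raise FormatError(f"{path}:{lineno}: non-finite value in {line!r}")
            rows.append(values)
    return rows


def read_work_file(path, dialect: str = "scalar") -> list[float]:
    """Read work values (kJ/mol) from a scalar or dhdl-table file.

    ``scalar``: one work value per non-comment line (``#`` comments).
    ``dhdl``: two whitespace-separated columns, lambda and dH/dlambda
    (kJ/mol), ``#``/``@`` lines ignored; the file holds one switching
    trajectory and is integrated to a single work value whose sign follows
    the lambda grid's orientation.
    """
    path = Path(path)
    if dialect == "scalar":
        rows = _parse_columns(path, 1, ("#",))
        if not rows:
            raise InsufficientDataError(f"{path}: no work values found")
        return [r[0] for r in rows]
    if dialect == "dhdl":
        rows = _parse_columns(path, 2, ("#", "@"))
        if not rows:
            raise InsufficientDataError(f"{path}: no dH/dlambda rows found")
        arr = np.asarray(rows)
        return [integrate_work(arr[:, 0], arr[:, 1])]
    raise InvalidParameterError(f"unknown dialect {dialect!r}")


def write_work_file(path, works, header: str | None = None) -> None:
    """Write scalar works, one per line, '#'-prefixed header."""
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for w in works:
            fh.write(f"{w:.17g}\n")


def write_dhdl_file(path, lambda_values, dhdl_values, header: str | None = None) -> None:
    """Write a two-column lambda / dH-dlambda table in the xvg dialect."""
    with open(path, "w") as fh:
        fh.write('@ title "dH/dlambda"\n')
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        for lam, dh in zip(lambda_values, dhdl_values, strict=True):
            fh.write(f"{lam:.17g} {dh:.17g}\n")


def write_worksets(worksets, directory, temperature: float | None = None) -> Path:
    """Write WorkSets as scalar work files plus a manifest CSV.

    One file per (WorkSet, direction); returns the manifest path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for idx, ws in enumerate(worksets):
        for direction, works in (("forward", ws.forward), ("reverse", ws.reverse)):
            if works.size == 0:
                continue
            name = f"work_{idx:04d}_{direction}.dat"
            write_work_file(directory / name, works)
            rows.append(
                {
                    "path": name,
                    "compound_i": ws.pair[0] if ws.pair else "",
                    "compound_j": ws.pair[1] if ws.pair else "",
                    "target": ws.target or "",
                    "leg": ws.leg or "",
                    "conformer": ws.conformer,
                    "direction": direction,
                    "temperature_K": ws.temperature,
                }
            )
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_work_directory(manifest_path, dialect: str = "scalar") -> list[WorkSet]:
    """Rebuild WorkSets from a manifest CSV and its work files.

    The manifest lists one row per file with the transformation tags and
    direction; rows sharing (compound_i, compound_j, target, leg,
    conformer) are merged into one WorkSet.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    table = pd.read_csv(manifest_path, dtype={"compound_i": str, "compound_j": str})
    missing = set(MANIFEST_COLUMNS) - set(table.columns)
    if missing:
        raise FormatError(f"manifest missing columns: {sorted(missing)}")
    worksets = []
    keys = ["compound_i", "compound_j", "target", "leg", "conformer"]
    for key, grp in table.groupby(keys, sort=True, dropna=False):
        ci, cj, target, leg, conformer = key
        by_dir: dict[str, list[float]] = {"forward": [], "reverse": []}
        for _, row in grp.iterrows():
            if row["direction"] not in by_dir:
                raise FormatError(f"unknown direction {row['direction']!r} in manifest")
            by_dir[row["direction"]].extend(read_work_file(base / row["path"], dialect))
        temp = (
            float(grp["temperature_K"].iloc[0])
            if "temperature_K" in grp
            else SIM_TEMPERATURE
        )
        worksets.append(
            WorkSet(
                forward=np.asarray(by_dir["forward"]),
                reverse=np.asarray(by_dir["reverse"]),
                temperature=temp,
                pair=(str(ci), str(cj)),
                target=str(target),
                leg=str(leg),
                conformer=str(conformer),
            )
        )
    return worksets


def read_inhibition_csv(path) -> list[InhibitionRecord]:
    """Read an inhibition table: compound,target,ic50_uM,ci_low_uM,ci_high_uM[,atp_uM,km_uM]."""
    table = pd.read_csv(path, dtype={"compound": str, "target": str})
    required = {"compound", "target", "ic50_uM", "ci_low_uM", "ci_high_uM"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"inhibition CSV missing columns: {sorted(missing)}")
    records = []
    for _, row in table.iterrows():
        km = row.get("km_uM")
        records.append(
            InhibitionRecord(
                compound=str(row["compound"]),
                target=str(row["target"]),
                ic50=float(row["ic50_uM"]),
                ci_low=float(row["ci_low_uM"]),
                ci_high=float(row["ci_high_uM"]),
                atp_conc=float(row["atp_uM"]) if "atp_uM" in table.columns else 1.0,
                km=float(km) if km is not None and pd.notna(km) else None,
            )
        )
    return records


def write_inhibition_csv(records, path) -> None:
    rows = []
    for r in records:
        row = {
            "compound": r.compound,
            "target": r.target,
            "ic50_uM": r.ic50,
            "ci_low_uM": r.ci_low,
            "ci_high_uM": r.ci_high,
            "atp_uM": r.atp_conc,
        }
        if r.km is not None:
            row["km_uM"] = r.km
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_cdk_inhibition() -> list[InhibitionRecord]:
    """The packaged CDK1/2/5/9 inhibition table for compounds 1-4.

    IC50 values (uM) with 95% CIs from in vitro kinase assays at 1 uM ATP;
    this is the experimental anchor the calculated ddG and dS tables are
    validated against.
    """
    resource = importlib.resources.files("neqsel") / "data" / "cdk_ic50.csv"
    with importlib.resources.as_file(resource) as path:
        return read_inhibition_csv(path)


def write_validation_report(results_by_mode: dict, path) -> None:
    """JSON report: {mode: {method: {slope, intercept, slope_ci, ...}}}."""
    payload = {
        mode: {method: res.to_dict() for method, res in by_method.items()}
        for mode, by_method in results_by_mode.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
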