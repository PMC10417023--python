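"""Relative selectivity changes between kinases.

A chemical modification that improves binding to one kinase more than to
another shifts selectivity.  For a compound pair (i, j) the selectivity
change toward kinase k relative to a reference kinase is

    dS_ij = ddG_ij^k - ddG_ij^ref

in kJ/mol: negative dS means the i-for-j substitution favours kinase k
over the reference kinase.  The two ddG errors add in quadrature, so dS
is intrinsically noisier than either ddG.  For the reference kinase
itself dS is identically zero and is excluded by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import hypot

import pandas as pd

from .exceptions import ContractError, InvalidParameterError

__all__ = ["SelectivityRecord", "delta_s", "selectivity_table", "ds_frame"]


@dataclass(frozen=True)
class SelectivityRecord:
    """Selectivity change dS (kJ/mol) of a compound pair toward one kinase."""

    pair: tuple[str, str]
    target_k: str
    reference_target: str
    dS: float
    se: float
    source: str

    def __post_init__(self) -> None:
        if self.target_k == self.reference_target:
            raise InvalidParameterError(
                "selectivity is defined against a different reference kinase"
            )
        if self.se < 0:
            raise InvalidParameterError(f"se must be >= 0, got {self.se}")


def delta_s(ddg_on_k, ddg_on_reference, source: str = "calculated") -> SelectivityRecord:
    """``dS = ddG^k - ddG^ref`` for one pair; SEs in quadrature.

    Both inputs need ``pair``, ``target``, ``ddg`` and ``se`` attributes
    (calculated :class:`~neqsel.ddg.TransformationDDG` and experimental
    :class:`~neqsel.affinity.ExperimentalDDG` both qualify) and must share
    the pair while differing in target.
    """
    if ddg_on_k.pair != ddg_on_reference.pair:
        raise ContractError(
            f"pairs differ: {ddg_on_k.pair} vs {ddg_on_reference.pair}"
        )
    if ddg_on_k.target == ddg_on_reference.target:
        raise ContractError(
            f"both ddG values are on target {ddg_on_k.target!r}; selectivity "
            "needs two different kinases"
        )
    return SelectivityRecord(
        pair=ddg_on_k.pair,
        target_k=ddg_on_k.target,
        reference_target=ddg_on_reference.target,
        dS=ddg_on_k.ddg - ddg_on_reference.ddg,
        se=hypot(ddg_on_k.se, ddg_on_reference.se),
        source=source,
    )


def _rebase_rows(row_i: pd.Series, row_j: pd.Series) -> tuple[float, float]:
    # ddG(j -> i) = ddG(ref -> i) - ddG(ref -> j); SE in quadrature.
    return (
        float(row_i["ddg"]) - float(row_j["ddg"]),
        hypot(float(row_i["se"]), float(row_j["se"])),
    )


def selectivity_table(
    ddg_table: pd.DataFrame,
    reference_target: str = "CDK2",
    reference_compound_i: str = "2",
    source: str = "calculated",
) -> tuple[pd.DataFrame, list[str]]:
    """dS for every pair (i = ``reference_compound_i``, j) and kinase.

    ``ddg_table`` is a long-format table of reference-compound
    transformations with columns ``compound_i, compound_j, target, ddg,
    se`` (plus ``method`` for calculated tables, carried through).  Pairs
    are first re-referenced so that compound i of every pair is
    ``reference_compound_i`` (via the common transformation reference),
    then dS is taken across targets against ``reference_target``.  On a
    4-compound x 4-kinase study this yields 3 pairs x 3 kinases = 9 rows
    per method.

    Returns ``(table, diagnostics)``; rows whose reference-target ddG is
    missing are skipped with a diagnostic.
    """
    required = {"compound_i", "compound_j", "target", "ddg", "se"}
    missing = required - set(ddg_table.columns)
    if missing:
        raise ContractError(f"ddg table missing columns: {sorted(missing)}")
    has_method = "method" in ddg_table.columns
    diagnostics: list[str] = []
    rows: list[dict] = []
    groups = ddg_table.groupby("method") if has_method else [(None, ddg_table)]
    for method, grp in groups:
        refs = set(grp["compound_j"])
        if len(refs) != 1:
            raise ContractError(
                f"expected a single transformation reference, found {sorted(refs)}"
            )
        trans_ref = refs.pop()
        by_ct = {(r["compound_i"], r["target"]): r for _, r in grp.iterrows()}
        compounds = sorted(set(grp["compound_i"]) | {trans_ref})
        targets = sorted(set(grp["target"]))
        if reference_compound_i not in compounds:
            diagnostics.append(
                f"method {method}: selectivity reference compound "
                f"{reference_compound_i!r} absent; skipped"
            )
            continue

        def pair_ddg(i: str, j: str, target: str):
            # ddG of transformation j -> i from the ref-compound table.
            if i == j:
                return 0.0, 0.0
            if j == trans_ref:
                r = by_ct.get((i, target))
                return (float(r["ddg"]), float(r["se"])) if r is not None else None
            if i == trans_ref:
                v = pair_ddg(j, i, target)
                return (-v[0], v[1]) if v is not None else None
            ri, rj = by_ct.get((i, target)), by_ct.get((j, target))
            if ri is None or rj is None:
                return None
            return _rebase_rows(ri, rj)

        for j in compounds:
            if j == reference_compound_i:
                continue
            for t in targets:
                if t == reference_target:
                    continue
                v_k = pair_ddg(reference_compound_i, j, t)
                v_ref = pair_ddg(reference_compound_i, j, reference_target)
                if v_k is None or v_ref is None:
                    diagnostics.append(
                        f"pair ({reference_compound_i}, {j}) target {t}"
                        + (f" method {method}" if method else "")
                        + ": missing ddG (target or reference-target); skipped"
                    )
                    continue
                row = {
                    "compound_i": reference_compound_i,
                    "compound_j": j,
                    "target": t,
                    "reference_target": reference_target,
                    "dS": v_k[0] - v_ref[0],
                    "se": hypot(v_k[1], v_ref[1]),
                    "source": f"{source}:{method}" if method else source,
                }
                if has_method:
                    row["method"] = method
                rows.append(row)
    return pd.DataFrame(rows), diagnostics


def ds_frame(records) -> pd.DataFrame:
    """Tidy DataFrame view of :class:`SelectivityRecord` entries."""
    return pd.DataFrame(
        [
            {
                "compound_i": r.pair[0],
                "compound_j": r.pair[1],
                "target": r.target_k,
                "reference_target": r.reference_target,
                "dS": r.dS,
                "se": r.se,
                "source": r.source,
            }
            for r in records
        ]
    )
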