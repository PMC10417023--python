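"""Assembling relative binding free energies from per-leg estimates.

The thermodynamic cycle gives the relative binding free energy of a
transformation as the alchemical dG in the protein complex minus that in
solvent:

    ddG = dG_complex - dG_solvent

with the two legs' bootstrap SEs combined in quadrature.  When a ligand
was started from several conformers, the conformer with the lowest ddG is
kept (ties broken by lexicographic conformer label) and its own SE is
carried unchanged.  Transformations are all run from a common reference
compound; pairs between two non-reference compounds are derived by
re-referencing:

    ddG(a -> b) = ddG(ref -> b) - ddG(ref -> a).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import pandas as pd

from .estimators import FreeEnergyEstimate
from .exceptions import ContractError, InvalidParameterError

__all__ = [
    "TransformationDDG",
    "leg_difference",
    "select_conformer",
    "rebase_pair",
    "assemble_matrix",
    "ddg_frame",
]


@dataclass(frozen=True)
class TransformationDDG:
    """ddG (kJ/mol) of one compound pair on one kinase.

    ``pair = (compound_i, compound_j)`` reads as the transformation
    j -> i; transformations from the study reference have the reference as
    ``compound_j``.
    """

    pair: tuple[str, str]
    target: str
    method: str
    ddg: float
    se: float = 0.0
    conformer: str = "default"
    selected: bool = False

    def __post_init__(self) -> None:
        if self.se < 0:
            raise InvalidParameterError(f"se must be >= 0, got {self.se}")


def leg_difference(
    complex_leg: FreeEnergyEstimate,
    solvent_leg: FreeEnergyEstimate,
    pair: tuple[str, str],
    target: str,
    conformer: str = "default",
) -> TransformationDDG:
    """Close the cycle: ``ddG = dG_complex - dG_solvent``, SEs in quadrature."""
    if complex_leg.method != solvent_leg.method:
        raise ContractError(
            f"leg methods differ: {complex_leg.method} vs {solvent_leg.method}"
        )
    if (
        complex_leg.temperature is not None
        and solvent_leg.temperature is not None
        and not math.isclose(complex_leg.temperature, solvent_leg.temperature)
    ):
        raise ContractError(
            f"leg temperatures differ: {complex_leg.temperature} vs "
            f"{solvent_leg.temperature}"
        )
    se_c = complex_leg.se or 0.0
    se_s = solvent_leg.se or 0.0
    return TransformationDDG(
        pair=pair,
        target=target,
        method=complex_leg.method,
        ddg=complex_leg.dG - solvent_leg.dG,
        se=math.hypot(se_c, se_s),
        conformer=conformer,
    )


def select_conformer(candidates) -> TransformationDDG:
    """Keep the lowest-ddG conformer of one (pair, target, method) cell.

    Ties break on the lexicographically smallest conformer label; the
    winner is returned with ``selected=True`` and its own SE unchanged.
    Idempotent and independent of candidate order.
    """
    candidates = list(candidates)
    if not candidates:
        raise ContractError("select_conformer needs at least one candidate")
    keys = {(c.pair, c.target, c.method) for c in candidates}
    if len(keys) > 1:
        raise ContractError(
            f"candidates span multiple (pair, target, method) cells: {keys}"
        )
    best = min(candidates, key=lambda c: (c.ddg, c.conformer))
    return replace(best, selected=True)


def rebase_pair(
    ddg_ref_to_a: TransformationDDG, ddg_ref_to_b: TransformationDDG
) -> TransformationDDG:
    """``ddG(a -> b) = ddG(ref -> b) - ddG(ref -> a)``, SEs in quadrature.

    Both inputs must be transformations from the same reference compound
    on the same target with the same method; the result's pair is
    ``(b, a)`` (the transformation a -> b).
    """
    a, ref_a = ddg_ref_to_a.pair
    b, ref_b = ddg_ref_to_b.pair
    if ref_a != ref_b:
        raise ContractError(f"reference compounds differ: {ref_a!r} vs {ref_b!r}")
    if ddg_ref_to_a.target != ddg_ref_to_b.target:
        raise ContractError(
            f"targets differ: {ddg_ref_to_a.target!r} vs {ddg_ref_to_b.target!r}"
        )
    if ddg_ref_to_a.method != ddg_ref_to_b.method:
        raise ContractError(
            f"methods differ: {ddg_ref_to_a.method!r} vs {ddg_ref_to_b.method!r}"
        )
    return TransformationDDG(
        pair=(b, a),
        target=ddg_ref_to_a.target,
        method=ddg_ref_to_a.method,
        ddg=ddg_ref_to_b.ddg - ddg_ref_to_a.ddg,
        se=math.hypot(ddg_ref_to_a.se, ddg_ref_to_b.se),
        conformer=ddg_ref_to_a.conformer,
    )


def assemble_matrix(estimates: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Full long-format ddG table from tagged per-leg estimates.

    ``estimates`` must carry columns ``compound_i, compound_j, target,
    leg, conformer, method, dG, se``.  For every (pair, target, method,
    conformer) with both legs present the cycle is closed; the lowest-ddG
    conformer is then selected per (pair, target, method).  Cells with a
    missing leg are reported in the diagnostics list, never imputed or
    silently dropped.

    Returns ``(table, diagnostics)`` where ``table`` has one row per
    selected (pair, target, method) with columns ``compound_i,
    compound_j, target, method, conformer, ddg, se``.
    """
    required = {"compound_i", "compound_j", "target", "leg", "conformer", "method", "dG", "se"}
    missing = required - set(estimates.columns)
    if missing:
        raise ContractError(f"estimates table missing columns: {sorted(missing)}")
    diagnostics: list[str] = []
    per_cell: dict[tuple, list[TransformationDDG]] = {}
    grouped = estimates.groupby(
        ["compound_i", "compound_j", "target", "method", "conformer"], sort=True
    )
    for (ci, cj, target, method, conformer), grp in grouped:
        legs = dict(zip(grp["leg"], grp.index))
        if "complex" not in legs or "solvent" not in legs:
            present = sorted(legs)
            diagnostics.append(
                f"pair ({ci}, {cj}) target {target} method {method} conformer "
                f"{conformer}: missing leg(s), have {present}"
            )
            continue
        if len(grp) > 2:
            diagnostics.append(
                f"pair ({ci}, {cj}) target {target} method {method} conformer "
                f"{conformer}: {len(grp)} leg rows, expected 2; using first of each"
            )
        row_c = grp.loc[legs["complex"]]
        row_s = grp.loc[legs["solvent"]]
        cand = TransformationDDG(
            pair=(ci, cj),
            target=target,
            method=method,
            ddg=float(row_c["dG"]) - float(row_s["dG"]),
            se=math.hypot(float(row_c["se"]), float(row_s["se"])),
            conformer=conformer,
        )
        per_cell.setdefault((ci, cj, target, method), []).append(cand)
    rows = []
    for key in sorted(per_cell):
        chosen = select_conformer(per_cell[key])
        rows.append(
            {
                "compound_i": chosen.pair[0],
                "compound_j": chosen.pair[1],
                "target": chosen.target,
                "method": chosen.method,
                "conformer": chosen.conformer,
                "ddg": chosen.ddg,
                "se": chosen.se,
            }
        )
    return pd.DataFrame(rows), diagnostics


def ddg_frame(records) -> pd.DataFrame:
    """Tidy DataFrame view of :class:`TransformationDDG` records."""
    return pd.DataFrame(
        [
            {
                "compound_i": r.pair[0],
                "compound_j": r.pair[1],
                "target": r.target,
                "method": r.method,
                "conformer": r.conformer,
                "ddg": r.ddg,
                "se": r.se,
                "selected": r.selected,
            }
            for r in records
        ]
    )
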