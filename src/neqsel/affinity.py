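"""Experimental relative binding free energies from inhibition data.

An ATP-competitive inhibitor's measured IC50 relates to its inhibition
constant through the Cheng-Prusoff equation

    Ki = IC50 / (1 + [ATP]/Km)

and two inhibition constants on the same kinase give the experimental
relative binding free energy

    ddG_exp(i, j) = R*T*ln(Ki_i / Ki_j).

Within one target at fixed substrate concentration the Cheng-Prusoff
factor cancels in the ratio, so ddG_exp is computed exactly from raw IC50
ratios whenever no Km value is supplied; an explicit Km is required only
to report absolute Ki values.

IC50 uncertainty enters through the 95% confidence interval of the assay
fit, treated as symmetric in log-IC50 (potency errors are multiplicative):
the log-scale SE is ``s = ln(ci_high/ci_low) / (2*z)`` with z = 1.959964,
and SEs of pairs and ratios propagate in quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._constants import ASSAY_TEMPERATURE, GAS_CONSTANT, Z_95
from .exceptions import ContractError, InvalidParameterError, KmUnavailableError

__all__ = [
    "InhibitionRecord",
    "ExperimentalDDG",
    "cheng_prusoff",
    "log_ic50_se",
    "ddg_exp_pair",
    "exp_table",
]


@dataclass(frozen=True)
class InhibitionRecord:
    """One IC50 measurement (uM) with its 95% CI for a compound on a kinase."""

    compound: str
    target: str
    ic50: float
    ci_low: float
    ci_high: float
    atp_conc: float = 1.0
    km: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.ci_low <= self.ic50 <= self.ci_high):
            raise InvalidParameterError(
                f"{self.compound}/{self.target}: require 0 < ci_low <= ic50 "
                f"<= ci_high, got ({self.ci_low}, {self.ic50}, {self.ci_high})"
            )
        if self.atp_conc <= 0:
            raise InvalidParameterError("atp_conc must be > 0")
        if self.km is not None and self.km <= 0:
            raise InvalidParameterError("km must be > 0 when present")


@dataclass(frozen=True)
class ExperimentalDDG:
    """Experimental ddG (kJ/mol) of a compound pair on one kinase."""

    pair: tuple[str, str]
    target: str
    ddg: float
    se: float
    temperature: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.ddg):
            raise InvalidParameterError("ddg must be finite")
        if self.se < 0:
            raise InvalidParameterError("se must be >= 0")


def cheng_prusoff(record: InhibitionRecord) -> float:
    """Inhibition constant Ki (uM) via ``Ki = IC50 / (1 + [ATP]/Km)``.

    Raises :class:`KmUnavailableError` when the record carries no Km —
    absolute Ki is never silently approximated by IC50.
    """
    if record.km is None:
        raise KmUnavailableError(
            f"no Km for target {record.target!r}; absolute Ki requires an "
            "explicit Km (ddG ratios within one target do not)"
        )
    return record.ic50 / (1.0 + record.atp_conc / record.km)


def log_ic50_se(record: InhibitionRecord) -> float:
    """SE of ln(IC50) from a CI symmetric in log space: ln(hi/lo)/(2z)."""
    return float(np.log(record.ci_high / record.ci_low) / (2.0 * Z_95))


def ddg_exp_pair(
    record_i: InhibitionRecord,
    record_j: InhibitionRecord,
    temperature: float = ASSAY_TEMPERATURE,
) -> ExperimentalDDG:
    """``ddG_exp = R*T*ln(Ki_i/Ki_j)`` for two records on the same kinase.

    Uses Cheng-Prusoff Ki values when both records carry a Km; otherwise
    the raw IC50 ratio, which is exact within one target at fixed [ATP]
    because the competition factor cancels.  The SE is
    ``R*T*sqrt(s_i^2 + s_j^2)`` with the log-scale SEs of the two CIs.
    """
    if record_i.target != record_j.target:
        raise ContractError(
            f"records are on different targets: {record_i.target!r} vs "
            f"{record_j.target!r}"
        )
    if temperature <= 0:
        raise InvalidParameterError("temperature must be positive")
    if record_i.km is not None and record_j.km is not None:
        ratio = cheng_prusoff(record_i) / cheng_prusoff(record_j)
    else:
        ratio = record_i.ic50 / record_j.ic50
    rt = GAS_CONSTANT * temperature
    se = rt * float(np.hypot(log_ic50_se(record_i), log_ic50_se(record_j)))
    return ExperimentalDDG(
        pair=(record_i.compound, record_j.compound),
        target=record_i.target,
        ddg=rt * float(np.log(ratio)),
        se=se,
        temperature=temperature,
    )


def exp_table(
    records,
    reference_compound: str = "1",
    temperature: float = ASSAY_TEMPERATURE,
) -> tuple[list[ExperimentalDDG], list[str]]:
    """Experimental ddG of every non-reference compound vs the reference.

    Pairs are oriented ``(compound, reference)`` so they line up with
    calculated transformations reference -> compound.  Targets on which the
    reference compound was not measured are skipped with a diagnostic.
    Returns ``(entries, diagnostics)``; entries are sorted by (target,
    compound) so the output is independent of input row order.
    """
    by_target: dict[str, dict[str, InhibitionRecord]] = {}
    for rec in records:
        by_target.setdefault(rec.target, {})[rec.compound] = rec
    entries: list[ExperimentalDDG] = []
    diagnostics: list[str] = []
    for target in sorted(by_target):
        recs = by_target[target]
        if reference_compound not in recs:
            diagnostics.append(
                f"target {target!r}: reference compound "
                f"{reference_compound!r} not measured; skipped"
            )
            continue
        ref = recs[reference_compound]
        for compound in sorted(recs):
            if compound == reference_compound:
                continue
            entries.append(ddg_exp_pair(recs[compound], ref, temperature))
    return entries, diagnostics


def exp_frame(entries) -> pd.DataFrame:
    """Tidy DataFrame view of :class:`ExperimentalDDG` entries."""
    return pd.DataFrame(
        [
            {
                "compound_i": e.pair[0],
                "compound_j": e.pair[1],
                "target": e.target,
                "ddg": e.ddg,
                "se": e.se,
                "temperature": e.temperature,
            }
            for e in entries
        ]
    )
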