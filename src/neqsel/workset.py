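"""Work samples from fast alchemical switching.

A :class:`WorkSet` holds the work values recorded while one ligand is
morphed into another during short non-equilibrium transitions, run in both
directions (state 0 -> 1 and 1 -> 0).  Reverse works are stored in the
reverse direction's own sign convention — the work done *during* the 1 -> 0
switch — and every estimator negates them internally where the theory
requires it.  The Crooks fluctuation theorem

    P_F(W) / P_R(-W) = exp(beta * (W - dG))

links the two distributions to the free energy difference dG of the
transformation; the estimators in :mod:`neqsel.estimators` exploit it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._constants import SIM_TEMPERATURE, beta as _beta
from .exceptions import FormatError, InvalidParameterError

__all__ = ["WorkSet", "integrate_work"]


@dataclass(frozen=True)
class WorkSet:
    """Forward and reverse work samples for one transformation leg.

    Parameters
    ----------
    forward, reverse
        Work values in kJ/mol.  Each array holds the work of its own
        direction's switching process; either may be empty, not both.
    temperature
        Temperature of the simulation, K.
    pair
        Transformation identifier ``(alternate, reference)``: the compound
        pair, read "reference -> alternate".
    target
        Protein (kinase) identifier, e.g. ``"CDK2"``.
    leg
        ``"complex"`` or ``"solvent"`` leg of the thermodynamic cycle.
    conformer
        Starting-conformer label (e.g. ``"sin"``, ``"anti"``, ``"default"``).
    """

    forward: np.ndarray
    reverse: np.ndarray
    temperature: float = SIM_TEMPERATURE
    pair: tuple[str, str] | None = None
    target: str | None = None
    leg: str | None = None
    conformer: str = "default"

    def __post_init__(self) -> None:
        fwd = np.asarray(self.forward, dtype=float).ravel()
        rev = np.asarray(self.reverse, dtype=float).ravel()
        object.__setattr__(self, "forward", fwd)
        object.__setattr__(self, "reverse", rev)
        if self.temperature <= 0:
            raise InvalidParameterError(
                f"temperature must be positive, got {self.temperature}"
            )
        if fwd.size == 0 and rev.size == 0:
            raise InvalidParameterError("at least one direction must be non-empty")
        if not (np.all(np.isfinite(fwd)) and np.all(np.isfinite(rev))):
            raise InvalidParameterError("all work values must be finite")

    @property
    def beta(self) -> float:
        """Inverse temperature 1/(R*T), mol/kJ."""
        return _beta(self.temperature)

    @property
    def n_forward(self) -> int:
        return int(self.forward.size)

    @property
    def n_reverse(self) -> int:
        return int(self.reverse.size)

    def swapped(self) -> "WorkSet":
        """The same data with the roles of the two directions exchanged.

        Describes the inverse transformation, so every two-sided estimator
        must negate its estimate on the swapped set (antisymmetry).
        """
        return replace(self, forward=self.reverse, reverse=self.forward)

    def resampled(self, rng: np.random.Generator) -> "WorkSet":
        """Bootstrap resample, with replacement within each direction."""
        fwd = self.forward
        rev = self.reverse
        if fwd.size:
            fwd = fwd[rng.integers(0, fwd.size, size=fwd.size)]
        if rev.size:
            rev = rev[rng.integers(0, rev.size, size=rev.size)]
        return replace(self, forward=fwd, reverse=rev)


def integrate_work(lambda_values, dhdl_values) -> float:
    """Work of one switching trajectory from its dH/dlambda trace.

    Trapezoidal integral of ``dhdl_values`` (kJ/mol) over the coupling
    parameter grid ``lambda_values``.  The sign follows the orientation of
    the grid: a descending grid (a 1 -> 0 switch) yields that direction's
    work in its own sign.

    Raises
    ------
    FormatError
        If the grids differ in length, are shorter than 2 points, or the
        lambda grid is not strictly monotone.
    """
    lam = np.asarray(lambda_values, dtype=float).ravel()
    dhdl = np.asarray(dhdl_values, dtype=float).ravel()
    if lam.size != dhdl.size:
        raise FormatError(
            f"lambda and dH/dlambda lengths differ: {lam.size} vs {dhdl.size}"
        )
    if lam.size < 2:
        raise FormatError("need at least 2 grid points to integrate work")
    d = np.diff(lam)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise FormatError("lambda grid must be strictly monotone")
    return float(np.trapezoid(dhdl, lam))
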