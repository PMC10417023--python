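"""Crooks-consistent synthetic work samples and full in-silico studies.

Real inputs to this pipeline come from short alchemical switching
simulations (work values) and from enzymatic inhibition assays (IC50
tables).  This module emulates both from a known ground truth so that
every downstream stage — estimation, cycle assembly, experimental
conversion, selectivity and validation — can be exercised and checked for
parameter recovery without molecular dynamics.

Work samples are Gaussian and satisfy the Crooks fluctuation theorem
exactly at the distribution level: for dissipation ``beta*sigma^2/2``,

    forward  ~ N(dG + beta*sigma^2/2, sigma^2)
    reverse  ~ N(-dG + beta*sigma^2/2, sigma^2)   (its own direction's sign)

so the negated reverse distribution is N(dG - beta*sigma^2/2, sigma^2) and
ln(P_F(W)/P_R(-W)) = beta*(W - dG).

IC50 measurements are derived from the same truth: Ki follows the binding
free energy through ``Ki = exp(dG/RT)`` (molar standard state, reported in
micromolar), the Cheng-Prusoff factor ``1 + [ATP]/Km`` converts Ki to
IC50, and measurement noise is log-normal.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._constants import (
    ASSAY_TEMPERATURE,
    GAS_CONSTANT,
    SIM_TEMPERATURE,
    Z_95,
    beta as _beta,
)
from .affinity import InhibitionRecord
from .exceptions import ConfigurationError, InvalidParameterError
from .workset import WorkSet

__all__ = ["SyntheticStudySpec", "SyntheticStudy", "sample_crooks_gaussian", "make_synthetic_study"]


def _stream(seed: int, *tags: str) -> np.random.Generator:
    # Deterministic per-record substream: root seed + CRC32 of the tag
    # string keeps streams independent of generation order.
    key = zlib.crc32("|".join(tags).encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def sample_crooks_gaussian(
    dG: float,
    sigma: float,
    n_forward: int,
    n_reverse: int,
    temperature: float = SIM_TEMPERATURE,
    seed: int | np.random.Generator | None = 0,
    **tags,
) -> WorkSet:
    """Draw Gaussian work samples consistent with the Crooks theorem.

    Parameters
    ----------
    dG
        True free energy difference of the transformation, kJ/mol.
    sigma
        Width of both work distributions, kJ/mol; the mean dissipated work
        is ``beta*sigma^2/2`` in each direction.
    n_forward, n_reverse
        Sample counts; either may be zero, not both.
    temperature
        Kelvin.
    seed
        Integer seed or an existing ``numpy`` Generator.
    **tags
        Passed through to :class:`~neqsel.workset.WorkSet` (pair, target,
        leg, conformer).
    """
    if sigma <= 0:
        raise InvalidParameterError(f"sigma must be positive, got {sigma}")
    if temperature <= 0:
        raise InvalidParameterError(f"temperature must be positive, got {temperature}")
    if n_forward < 0 or n_reverse < 0 or (n_forward == 0 and n_reverse == 0):
        raise InvalidParameterError(
            f"need non-negative counts with at least one positive, got "
            f"({n_forward}, {n_reverse})"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dissipation = _beta(temperature) * sigma**2 / 2.0
    fwd = rng.normal(dG + dissipation, sigma, size=n_forward)
    rev = rng.normal(-dG + dissipation, sigma, size=n_reverse)
    return WorkSet(forward=fwd, reverse=rev, temperature=temperature, **tags)


@dataclass(frozen=True)
class SyntheticStudySpec:
    """Ground-truth description of a synthetic compound x kinase study.

    ``true_dG[(compound, target)]`` are absolute binding free energies in
    kJ/mol; ``solvent_dG[compound]`` is the solvation-leg dG of the
    transformation reference -> compound (target-independent, as the
    solvent leg of the thermodynamic cycle is).  Defaults mirror a small
    kinase-inhibitor study: four compounds against four CDKs, 100 switches
    per direction, 2 kJ/mol work spread, 1 uM ATP assay.
    """

    compounds: tuple[str, ...] = ("1", "2", "3", "4")
    reference_compound: str = "1"
    targets: tuple[str, ...] = ("CDK1", "CDK2", "CDK5", "CDK9")
    reference_target: str = "CDK2"
    true_dG: dict[tuple[str, str], float] | None = None
    solvent_dG: dict[str, float] | None = None
    work_sigma: float = 2.0
    n_forward: int = 100
    n_reverse: int = 100
    ic50_noise_sd: float = 0.1
    atp_conc: float = 1.0
    km: float | dict[str, float] = 10.0
    temperature: float = SIM_TEMPERATURE
    assay_temperature: float = ASSAY_TEMPERATURE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.work_sigma <= 0:
            raise InvalidParameterError("work_sigma must be > 0")
        if self.n_forward < 1 or self.n_reverse < 1:
            raise InvalidParameterError("n_forward and n_reverse must be >= 1")
        if self.ic50_noise_sd < 0:
            raise InvalidParameterError("ic50_noise_sd must be >= 0")
        if self.atp_conc <= 0:
            raise InvalidParameterError("atp_conc must be > 0")
        kms = self.km.values() if isinstance(self.km, dict) else [self.km]
        if any(k <= 0 for k in kms):
            raise InvalidParameterError("km must be > 0")
        if self.reference_compound not in self.compounds:
            raise ConfigurationError(
                f"reference compound {self.reference_compound!r} not in compounds"
            )
        if self.reference_target not in self.targets:
            raise ConfigurationError(
                f"reference target {self.reference_target!r} not in targets"
            )
        if self.true_dG is None:
            object.__setattr__(self, "true_dG", self._default_true_dg())
        if self.solvent_dG is None:
            object.__setattr__(
                self,
                "solvent_dG",
                {c: 5.0 * (i + 1) for i, c in enumerate(self.alternates)},
            )
        missing = [
            (c, t)
            for c in self.compounds
            for t in self.targets
            if (c, t) not in self.true_dG
        ]
        if missing:
            raise ConfigurationError(f"true_dG missing entries for {missing}")
        missing_solv = [c for c in self.alternates if c not in self.solvent_dG]
        if missing_solv:
            raise ConfigurationError(f"solvent_dG missing entries for {missing_solv}")

    @property
    def alternates(self) -> tuple[str, ...]:
        """Compounds other than the reference (one transformation each)."""
        return tuple(c for c in self.compounds if c != self.reference_compound)

    def _default_true_dg(self) -> dict[tuple[str, str], float]:
        # Binding free energies around -35 kJ/mol (sub-uM Ki at 303 K) with
        # compound- and target-dependent spread of a few kJ/mol, the scale
        # over which real congeneric-series ddG values vary.
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0xDD61]))
        out = {}
        for c in self.compounds:
            for t in self.targets:
                out[(c, t)] = float(-35.0 + rng.uniform(-4.0, 4.0))
        return out

    def km_for(self, target: str) -> float:
        return self.km[target] if isinstance(self.km, dict) else self.km


@dataclass(frozen=True)
class SyntheticStudy:
    """Output bundle of :func:`make_synthetic_study`."""

    spec: SyntheticStudySpec
    worksets: tuple[WorkSet, ...]
    inhibition: tuple[InhibitionRecord, ...]
    ddg_truth: pd.DataFrame
    ds_truth: pd.DataFrame


def make_synthetic_study(spec: SyntheticStudySpec) -> SyntheticStudy:
    """Generate work samples, noisy IC50 records and the truth tables.

    For each (pair, target) the complex-leg WorkSet is centred on
    ``solvent_dG + (dG[alt, target] - dG[ref, target])`` and the solvent
    leg on ``solvent_dG`` alone, so the thermodynamic cycle closes on the
    true ddG.  IC50s follow the Cheng-Prusoff relation from the same truth
    with multiplicative log-normal noise, and their 95% CI is symmetric in
    log space consistent with ``ic50_noise_sd``.

    The ``ddg_truth`` table holds the true ddG of every (alternate,
    reference) pair per target; ``ds_truth`` holds the true selectivity
    shift for every ordered compound pair and non-reference target.
    """
    ref = spec.reference_compound
    worksets: list[WorkSet] = []
    for alt in spec.alternates:
        pair = (alt, ref)
        # Solvent-leg truth is target-independent (the solvent leg of the
        # cycle does not see the protein); samples are drawn per target so
        # each (pair, target) cell closes its own cycle.
        solv_dg = spec.solvent_dG[alt]
        for t in spec.targets:
            complex_dg = solv_dg + spec.true_dG[(alt, t)] - spec.true_dG[(ref, t)]
            for leg, dg in (("complex", complex_dg), ("solvent", solv_dg)):
                worksets.append(
                    sample_crooks_gaussian(
                        dg,
                        spec.work_sigma,
                        spec.n_forward,
                        spec.n_reverse,
                        temperature=spec.temperature,
                        seed=_stream(spec.seed, "work", alt, t, leg),
                        pair=pair,
                        target=t,
                        leg=leg,
                    )
                )

    rt = GAS_CONSTANT * spec.assay_temperature
    records: list[InhibitionRecord] = []
    for c in spec.compounds:
        for t in spec.targets:
            ki_uM = np.exp(spec.true_dG[(c, t)] / rt) * 1e6
            ic50_true = ki_uM * (1.0 + spec.atp_conc / spec.km_for(t))
            rng = _stream(spec.seed, "ic50", c, t)
            noise = rng.normal(0.0, spec.ic50_noise_sd) if spec.ic50_noise_sd else 0.0
            ic50 = ic50_true * float(np.exp(noise))
            half_width = Z_95 * spec.ic50_noise_sd
            records.append(
                InhibitionRecord(
                    compound=c,
                    target=t,
                    ic50=ic50,
                    ci_low=ic50 * float(np.exp(-half_width)),
                    ci_high=ic50 * float(np.exp(half_width)),
                    atp_conc=spec.atp_conc,
                    km=spec.km_for(t),
                )
            )

    ddg_rows = [
        {
            "compound_i": alt,
            "compound_j": ref,
            "target": t,
            "ddg_true": spec.true_dG[(alt, t)] - spec.true_dG[(ref, t)],
        }
        for alt in spec.alternates
        for t in spec.targets
    ]
    ddg_truth = pd.DataFrame(ddg_rows)

    def _sel(c: str, t: str) -> float:
        return spec.true_dG[(c, t)] - spec.true_dG[(c, spec.reference_target)]

    ds_rows = [
        {
            "compound_i": i,
            "compound_j": j,
            "target": t,
            "reference_target": spec.reference_target,
            "ds_true": _sel(i, t) - _sel(j, t),
        }
        for i in spec.compounds
        for j in spec.compounds
        if i != j
        for t in spec.targets
        if t != spec.reference_target
    ]
    ds_truth = pd.DataFrame(ds_rows)

    return SyntheticStudy(
        spec=spec,
        worksets=tuple(worksets),
        inhibition=tuple(records),
        ddg_truth=ddg_truth,
        ds_truth=ds_truth,
    )
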