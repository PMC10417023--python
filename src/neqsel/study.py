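"""End-to-end study model: work samples + inhibition data -> validated predictions.

:class:`SelectivityStudy` is the package's top-level modelling object, in
the mould of a statsmodels model: it is built from data (WorkSets and
inhibition records, or a synthetic study specification) plus a
:class:`~neqsel.io.RunConfig`, and :meth:`SelectivityStudy.fit` runs the
whole chain —

  estimate dG per leg (JAR/CGI/BAR with bootstrap SEs)
  -> close thermodynamic cycles and select conformers (ddG table)
  -> convert IC50s to experimental ddG
  -> compute calculated and experimental selectivity shifts (dS)
  -> errors-in-variables validation (Deming slope/CI, R^2, RMSE, MAE)

— returning a :class:`StudyResults` that carries every intermediate table,
the per-method regression results and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .affinity import exp_frame, exp_table
from .ddg import assemble_matrix
from .deming import DemingResults, validate
from .estimators import estimate_all
from .exceptions import ContractError
from .io import RunConfig
from .selectivity import selectivity_table
from .synthetic import SyntheticStudy, SyntheticStudySpec, make_synthetic_study

__all__ = ["SelectivityStudy", "StudyResults"]


@dataclass(frozen=True)
class StudyResults:
    """Every table and regression the fitted study produced.

    Attributes
    ----------
    estimates : per-(leg, conformer, method) dG estimates with SEs.
    ddg_calc : selected calculated ddG per (pair, target, method).
    ddg_exp : experimental ddG per (compound, reference) pair and target.
    ds_calc, ds_exp : selectivity tables, re-referenced to the
        configured selectivity compound.
    ddg_validation, ds_validation : per-method Deming results.
    ddg_points, ds_points : the joined (x, y) point clouds behind them.
    diagnostics : human-readable notes on skipped/incomplete cells.
    """

    config: RunConfig
    estimates: pd.DataFrame
    ddg_calc: pd.DataFrame
    ddg_exp: pd.DataFrame
    ds_calc: pd.DataFrame
    ds_exp: pd.DataFrame
    ddg_validation: dict[str, DemingResults]
    ds_validation: dict[str, DemingResults]
    ddg_points: pd.DataFrame
    ds_points: pd.DataFrame
    diagnostics: tuple[str, ...] = ()

    def summary(self) -> str:
        lines = [
            "Non-equilibrium relative binding free energy study",
            "=" * 58,
            f"methods: {', '.join(sorted(self.ddg_validation))}   "
            f"T(exp) = {self.config.temperature_K} K   "
            f"n_boot = {self.config.n_boot}   seed = {self.config.seed}",
            f"ddG cells: {len(self.ddg_calc)} calculated, "
            f"{len(self.ddg_exp)} experimental; "
            f"dS cells: {len(self.ds_calc)} calculated, {len(self.ds_exp)} experimental",
            "",
            "ddG(calc) vs ddG(exp), kJ/mol",
            "-" * 58,
        ]
        for method in sorted(self.ddg_validation):
            lines.append(self.ddg_validation[method].summary())
            lines.append("")
        lines += ["dS(calc) vs dS(exp), kJ/mol", "-" * 58]
        for method in sorted(self.ds_validation):
            lines.append(self.ds_validation[method].summary())
            lines.append("")
        if self.diagnostics:
            lines += ["diagnostics", "-" * 58, *self.diagnostics]
        return "\n".join(lines)


class SelectivityStudy:
    """Model of one compound-series x kinase-panel NEQ study.

    Parameters
    ----------
    worksets
        Forward/reverse work samples, one WorkSet per (pair, target, leg,
        conformer); every WorkSet must carry its tags.
    inhibition
        IC50 records covering the same compounds and targets.
    config
        Run configuration (reference compound/target, temperature for the
        experimental conversion, bootstrap size, seed, methods).
    """

    def __init__(self, worksets, inhibition, config: RunConfig | None = None):
        self.worksets = tuple(worksets)
        self.inhibition = tuple(inhibition)
        self.config = config or RunConfig()
        for ws in self.worksets:
            if ws.pair is None or ws.target is None or ws.leg is None:
                raise ContractError(
                    "every WorkSet must carry pair, target and leg tags"
                )
        self._external_ddg: pd.DataFrame | None = None
        self._truth: SyntheticStudy | None = None

    @classmethod
    def from_synthetic(
        cls, spec: SyntheticStudySpec, config: RunConfig | None = None
    ) -> "SelectivityStudy":
        """Build from a synthetic ground-truth specification.

        The resulting study keeps the truth tables (``.truth``) so fitted
        results can be checked for parameter recovery.
        """
        synth = make_synthetic_study(spec)
        config = config or RunConfig(
            seed=spec.seed,
            temperature_K=spec.assay_temperature,
            sim_temperature_K=spec.temperature,
            reference_compound=spec.reference_compound,
            reference_target=spec.reference_target,
        )
        study = cls(synth.worksets, synth.inhibition, config)
        study._truth = synth
        return study

    @classmethod
    def from_external_ddg(
        cls, ddg_calc: pd.DataFrame, inhibition, config: RunConfig | None = None
    ) -> "SelectivityStudy":
        """Validation-only study from an externally computed ddG table.

        ``ddg_calc`` must have columns ``compound_i, compound_j, target,
        method, ddg, se`` (transformations from the reference compound).
        No work samples are consumed; :meth:`fit` starts at the
        selectivity/validation stages.
        """
        study = cls.__new__(cls)
        study.worksets = ()
        study.inhibition = tuple(inhibition)
        study.config = config or RunConfig()
        study._external_ddg = ddg_calc.copy()
        study._truth = None
        return study

    @property
    def truth(self) -> SyntheticStudy | None:
        """Ground-truth bundle when built from a synthetic spec, else None."""
        return self._truth

    def fit(self, n_boot: int | None = None) -> StudyResults:
        """Run estimation, assembly, conversion, selectivity and validation.

        ``n_boot`` overrides the configured bootstrap size; ``n_boot=0``
        disables the bootstrap (SEs fall back to 0 and the Deming stage's
        zero-SE rule applies).
        """
        cfg = self.config
        if n_boot is None:
            n_boot = cfg.n_boot
        diagnostics: list[str] = []

        if self._external_ddg is not None:
            ddg_calc = self._external_ddg
            est_frame = pd.DataFrame()
        else:
            est_rows = []
            for idx, ws in enumerate(self.worksets):
                boot = n_boot if n_boot and n_boot >= 2 else None
                seed = cfg.seed + 104729 * (idx + 1)
                estimates, skipped = estimate_all(
                    ws, methods=cfg.methods, n_boot=boot, seed=seed
                )
                for reason in skipped.values():
                    diagnostics.append(
                        f"{ws.pair} {ws.target} {ws.leg}/{ws.conformer}: {reason}"
                    )
                for est in estimates:
                    est_rows.append(
                        {
                            "compound_i": ws.pair[0],
                            "compound_j": ws.pair[1],
                            "target": ws.target,
                            "leg": ws.leg,
                            "conformer": ws.conformer,
                            "method": est.method,
                            "dG": est.dG,
                            "se": est.se if est.se is not None else 0.0,
                            "n_F": est.n_forward,
                            "n_R": est.n_reverse,
                        }
                    )
            est_frame = pd.DataFrame(est_rows)
            ddg_calc, ddg_diag = assemble_matrix(est_frame)
            diagnostics.extend(ddg_diag)

        entries, exp_diag = exp_table(
            self.inhibition, cfg.reference_compound, cfg.temperature_K
        )
        diagnostics.extend(exp_diag)
        ddg_exp = exp_frame(entries)

        ds_calc, ds_diag_c = selectivity_table(
            ddg_calc,
            reference_target=cfg.reference_target,
            reference_compound_i=cfg.selectivity_compound,
            source="calculated",
        )
        ds_exp, ds_diag_e = selectivity_table(
            ddg_exp,
            reference_target=cfg.reference_target,
            reference_compound_i=cfg.selectivity_compound,
            source="experimental",
        )
        diagnostics.extend(ds_diag_c)
        diagnostics.extend(ds_diag_e)

        ddg_results, ddg_points, join_diag = validate(ddg_calc, ddg_exp)
        diagnostics.extend(join_diag)
        ds_results, ds_points, ds_join_diag = validate(
            ds_calc.drop(columns=["source"]),
            ds_exp.drop(columns=["source"]),
        )
        diagnostics.extend(ds_join_diag)

        return StudyResults(
            config=cfg,
            estimates=est_frame,
            ddg_calc=ddg_calc,
            ddg_exp=ddg_exp,
            ds_calc=ds_calc,
            ds_exp=ds_exp,
            ddg_validation=ddg_results,
            ds_validation=ds_results,
            ddg_points=ddg_points,
            ds_points=ds_points,
            diagnostics=tuple(diagnostics),
        )
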