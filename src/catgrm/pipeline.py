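"""End-to-end scale-development pipeline.

Runs the full scale-development sequence on one response matrix:

1. descriptive screens (complete cases, unused categories, item-remainder),
2. IRT assumption screens (unidimensionality, local dependence, monotonicity),
3. GRM calibration with never-modal-category and S-X2 item-fit exclusions,
4. DIF screening between the two metadata groups,
5. recalibration on the final item set (theta_true), Cronbach's alpha,
   CAT simulation, and validity statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import calibration as cal
from .cat import CATConfig
from .io import RunConfig
from .screening import ResponseMatrix, ScreeningReport, run_screening
from .simulation import SimulationResult, ValidityResult, concurrent_validity, discriminant_validity, simulate_cat


@dataclass
class PipelineResult:
    screening: ScreeningReport
    calibration: cal.CalibrationResult
    simulation: SimulationResult
    validity: ValidityResult
    data_final: ResponseMatrix

    def funnel(self) -> dict[str, str]:
        """item_id -> stage responsible for its exclusion."""
        return dict(self.screening.excluded_items)

    def to_dict(self) -> dict:
        return {
            "screening": self.screening.to_dict(),
            "n_items_final": len(self.calibration.bank),
            "alpha": self.calibration.alpha,
            "simulation": self.simulation.summary(),
        }


def run_pipeline(data: ResponseMatrix, config: RunConfig | None = None) -> PipelineResult:
    config = config or RunConfig()

    data_screened, report = run_screening(
        data,
        item_remainder_threshold=config.item_remainder,
        pca_first_proportion=config.pca_first_proportion,
        pca_ratio=config.pca_ratio,
        residual_threshold=config.residual_correlation,
        scalability_threshold=config.scalability,
    )

    # GRM-based screens: calibrate, then never-modal, S-X2, DIF
    result = cal.fit_grm(data_screened, tol=config.em_tol, max_iter=config.em_max_iter)

    never_modal = cal.never_modal_category_screen(result.bank)
    keep = [i for i in data_screened.item_ids if i not in never_modal]
    report.record("never_modal_category", data_screened.n_items, len(keep),
                  {k: float(len(v)) for k, v in never_modal.items()})
    data_screened = data_screened.select_items(keep)
    bank = result.bank.subset(keep)

    fit = cal.s_x2_item_fit(bank, data_screened, alpha=config.item_fit_alpha)
    keep = [i for i in data_screened.item_ids if not fit.loc[i, "excluded"]]
    report.record("item_fit", data_screened.n_items, len(keep),
                  {i: float(fit.loc[i, "statistic"]) for i in fit.index[fit["excluded"]]})
    data_screened = data_screened.select_items(keep)

    if data_screened.group is not None and len(np.unique(data_screened.group)) == 2:
        dif = cal.dif_screen(data_screened, alpha=config.dif_alpha)
        keep = [i for i in data_screened.item_ids if not dif.loc[i, "excluded"]]
        report.record("dif", data_screened.n_items, len(keep),
                      {i: float(dif.loc[i, "statistic"]) for i in dif.index[dif["excluded"]]})
        data_screened = data_screened.select_items(keep)
    else:
        dif = None
        report.record("dif", data_screened.n_items, data_screened.n_items, {}, skipped=True)

    # recalibrate on the final item set; these MAP scores are theta_true
    final = cal.fit_grm(data_screened, tol=config.em_tol, max_iter=config.em_max_iter)
    final.item_fit = fit
    final.dif = dif
    final.alpha = cal.cronbach_alpha(data_screened)

    cat_config = CATConfig(sem_threshold=config.sem_threshold,
                           min_items=config.min_items, max_items=config.max_items)
    sim = simulate_cat(final.bank, final.theta_values, cat_config, seed=config.seed)

    validity = ValidityResult()
    theta_est = sim.per_respondent["theta_est"].to_numpy()
    if data_screened.external_scores is not None:
        validity.concurrent = concurrent_validity(theta_est, data_screened.external_scores)
    if data_screened.group is not None and len(np.unique(data_screened.group)) == 2:
        validity.discriminant = discriminant_validity(theta_est, data_screened.group)

    return PipelineResult(report, final, sim, validity, data_screened)
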