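"""High-level orchestration of the two-stage predictive framework.

Glues the stages together: first-stage fits, age meta-variables, composite
vulnerability indices, meta-regression with BLUPs, kriging of the residuals,
and composed predictions at target locations.  Used by the command-line
interface, the validation study and the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import first_stage
from .age_meta import age_meta_variable, attach_age_values
from .basis import CrossBasisSpec
from .metareg import MetaFit, blup, build_design, fit_metareg
from .predict import find_mmt, predict_unobserved
from .vulnerability import city_average_response, fit_components


@dataclass
class TwoStageResult:
    coefs: list
    comp_model: object
    scores: pd.DataFrame
    design: object
    fit: MetaFit
    blups: object
    spec: CrossBasisSpec = field(repr=False, default=None)


def age_values_for(study, locations):
    """Age meta-variable per (location, age group) from the demography table."""
    demo = study.demography[study.demography["location"].isin(locations)]
    bounds = study.age_group_bounds
    vals = {}
    for (loc, lab), block in demo.groupby(["location", "age_group"]):
        lo, up = bounds[lab]
        deaths = pd.Series(block["deaths"].to_numpy(),
                           index=block["age"].to_numpy())
        le = float(block["life_expectancy"].iloc[0]) if up is None else None
        vals[(loc, lab)] = age_meta_variable((lo, up), deaths_by_age=deaths,
                                             life_expectancy=le)
    return vals


def run_two_stage(study, K=6, locations=None, spec=None, method="reml",
                  time_df_per_year=7, pls_method="pls",
                  coefs=None) -> TwoStageResult:
    """Steps 1-4: first stage, age meta-variable, vulnerability components,
    predictive meta-regression with BLUPs.  Precomputed reduced coefficients
    (with age values attached) can be passed to skip the first stage."""
    spec = spec or CrossBasisSpec()
    if coefs is None:
        coefs = first_stage.run_all(study, spec,
                                    time_df_per_year=time_df_per_year,
                                    locations=locations)
        attach_age_values(coefs, study.demography, study.age_group_bounds)
    response = city_average_response(coefs)
    comp = fit_components(study.metavars.loc[response.index], response,
                          K=K, method=pls_method)
    design = build_design(coefs, comp.training_scores)
    fit = fit_metareg(coefs, design, method=method)
    blups = blup(fit, coefs, design)
    return TwoStageResult(coefs=coefs, comp_model=comp,
                          scores=comp.training_scores, design=design,
                          fit=fit, blups=blups, spec=spec)


def predict_targets(study, ts: TwoStageResult, target_ids=None,
                    kriging_method="ordinary", mmt_bounds=(1.0, 99.0)):
    """Steps 5-6: krige the BLUP residuals and compose predictions at the
    target (default: unobserved) locations, centring each predicted curve at
    its minimum-mortality temperature."""
    loc = study.locations
    if target_ids is None:
        target_ids = list(loc.loc[~loc["observed"], "location"])
    age_vals = age_values_for(study, target_ids)
    preds, kriged, vmodels = predict_unobserved(
        ts.fit, ts.comp_model, ts.blups, loc, study.metavars, age_vals,
        target_ids=target_ids, kriging_method=kriging_method)

    temps = {l: g["temp"].to_numpy()
             for l, g in study.series[study.series["location"].isin(target_ids)]
             .groupby("location")}
    specs = {}
    for pr in preds:
        if pr.location not in specs:
            specs[pr.location] = ts.spec.resolve(temps[pr.location])
        find_mmt(pr, specs[pr.location], temps[pr.location], bounds=mmt_bounds)
    return preds, kriged, vmodels, specs
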