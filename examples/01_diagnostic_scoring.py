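"""Diagnostic scoring of a synthetic analog series.

Generates a series with known SAR structure, enumerates a close-in
virtual-analog pool, calibrates the neighborhood radius, computes the
coverage/density/saturation/progression scores with resampling, and
turns them into a development-stage call with a design recommendation.
"""

import numpy as np

from analogscope import (
    RunConfig,
    SeriesGeneratorSpec,
    calibrate_radius,
    classify_stage,
    descriptor_matrix,
    fit_standardizer,
    generate_series,
    generate_va_pool,
    recommend_strategy,
    score_with_resampling,
)

synth = generate_series(
    SeriesGeneratorSpec(
        n_sites=3, substituents_per_site=8, n_eas=40, noise_sd=0.2, seed=17
    )
)
series = synth.series
print(f"series core: {series.core.core_smiles}")
print(f"{series.n_analogs} existing analogs, {series.n_sites} substitution sites")

pool = generate_va_pool(synth, 400, "recombination", seed=18)
print(f"virtual-analog pool: {len(pool)} unique close-in analogs")

eas_m = descriptor_matrix(series.analogs)
pool_m = descriptor_matrix(pool)
space = fit_standardizer(np.vstack([eas_m, pool_m]))
radius = calibrate_radius(eas_m, pool_m, space, target_quantile=0.05)
print(f"calibrated neighborhood radius: {radius:.3f} (5% distance quantile)")

config = RunConfig(radius=radius, n_resamples=10, sample_size=200, seed=1)
report = score_with_resampling(series.analogs, pool, config)
print(
    f"C={report.c_mean:.2f} (±{report.c_sd:.2f})  "
    f"D={report.d_mean:.2f} (±{report.d_sd:.2f})  "
    f"S={report.s_mean:.2f} (±{report.s_sd:.2f})  "
    f"P={report.p_mean:.2f} (±{report.p_sd:.2f})"
)

assessment = classify_stage(report)
print(f"stage: {assessment.stage_label} — {assessment.rationale}")
print(f"recommended design strategies (best first): {recommend_strategy(assessment)}")
print(
    "\nC is the fraction of virtual analogs inside any existing analog's "
    "neighborhood, D grows with neighborhood overlap, S is their harmonic "
    "mean (chemical saturation), and P is the potency spread among "
    "overlapping neighborhoods (SAR progression, in pIC50 log units)."
)
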