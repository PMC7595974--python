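"""Free-Wilson quartets: local additivity predictions for designed analogs.

On a strictly additive, noise-free series the quartet prediction
pot(x) + pot(y) - pot(ref) recovers every unexplored combination's
potency exactly; the example verifies this against the generator's
ground truth.
"""

import numpy as np

from analogscope import (
    SeriesGeneratorSpec,
    compute_mmps,
    find_quartets,
    fw_ea_fraction,
    generate_fw_vas,
    generate_series,
    predict_all_targets,
)

synth = generate_series(
    SeriesGeneratorSpec(n_sites=3, substituents_per_site=6, n_eas=30, seed=101)
)
series = synth.series

mmps = compute_mmps(series)
quartets = find_quartets(series)
fw_vas = generate_fw_vas(series, quartets)
n_member, frac = fw_ea_fraction(series, quartets)

print(f"matched molecular pairs: {len(mmps)}")
print(f"Free-Wilson quartets:    {len(quartets)}")
print(f"FW virtual analogs:      {len(fw_vas)} (unexplored substituent combinations)")
print(f"analogs in FW neighborhoods: {n_member}/{series.n_analogs} ({frac * 100:.0f}%)")

predictions = predict_all_targets(series, quartets, status="FW_VA")
errors = [
    abs(mean - synth.truth.clean_potency(
        next(q for q in quartets if q.target_smiles == smi).target_subs
    ))
    for smi, (mean, sd, n) in predictions.items()
]
print(f"max |prediction - ground truth| over {len(errors)} FW analogs: "
      f"{max(errors):.2e} pIC50")
best = max(predictions.items(), key=lambda kv: kv[1][0])
print(f"top-ranked FW analog: {best[0]} predicted pIC50 {best[1][0]:.2f} "
      f"(sd {best[1][1]:.2f} over {best[1][2]} quartets)")
print(
    "\nEach quartet is a local mini-QSAR from three measured analogs; zero "
    "error here confirms exact additivity recovery, and the aggregate sd "
    "flags targets whose supporting quartets disagree (non-additivity)."
)
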