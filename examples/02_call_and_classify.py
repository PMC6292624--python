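"""Array intensities -> genotype calls -> haplogroup classification.

Simulates intensity records with realistic cluster noise, a 1% low-intensity
fraction and 0.5% heteroplasmic AB-band records, calls genotypes with the
standard thresholds (Norm R >= 0.08, theta clusters at 0.25/0.75, 97% sample
call rate), classifies every sample, and reports how often the generating
haplogroup is recovered at each level.
"""

import numpy as np

from mitocline import (
    CallerThresholds,
    bundled_tree,
    call_matrix,
    classify_cohort,
    default_panel,
    denmark_model,
    sample_qc,
    simulate_cohort,
    simulate_genotypes,
    simulate_intensities,
)

tree = bundled_tree()
panel = default_panel(tree)
tree.attach_panel(panel)

cohort = simulate_cohort(denmark_model(), tree, n=1500, seed=7)
geno = simulate_genotypes(cohort, tree, panel, private_mut_rate=0.002,
                          missing_rate=0.005, seed=8)
records = simulate_intensities(geno, noise_sd=0.04, lowintensity_rate=0.01,
                               ab_rate=0.005, seed=9)

t = CallerThresholds()
called = call_matrix(records, panel, t, sample_ids=geno.sample_ids)
kept, removed = sample_qc(called, t)
print(f"samples kept after 97% call-rate QC: {kept.n_samples}/{called.n_samples}")
print(f"mean call rate: {kept.call_rates().mean():.4f}")

calls, unassigned = classify_cohort(kept, tree)
truth = dict(zip(cohort["sample_id"], cohort["true_hg"]))
recovered = np.mean([c.deepest == truth[c.sample_id] for c in calls])
print(f"\nexact haplogroup recovery: {100 * recovered:.1f}%")
print("unassigned fraction per level:")
print((100 * unassigned).round(2).to_string())
print("\nUnassigned rates of a few percent at the deeper levels mirror what")
print("a 418-SNP panel can resolve; macro-level assignment is near-complete.")
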