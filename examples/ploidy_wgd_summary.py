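"""Per-sample genome summaries: ploidy, WGD score, CIN class, CNA burden.

The WGD score counts autosome arms whose median allele-specific state is
consistent with a duplication history (2m0 copy-neutral LOH or balanced 4m2)
minus arms consistent with none (2m1, 4m1): a pure diploid scores -44, a
pure doubled genome +44, and real cohorts split into two modes.
"""

from cnascan import (
    SimulationConfig,
    simulate_cohort,
    summarize_cohort,
    two_component_separation,
)

cohort = simulate_cohort(SimulationConfig(n_disseminated=40, n_control=40, seed=3))
summary = summarize_cohort(cohort.profiles, cohort.config.arms)

print(summary.head(8).to_string(index=False,
                                float_format=lambda v: f"{v:.2f}"))

calls = summary.wgd_call.to_numpy()
truth = cohort.truth.wgd.to_numpy()
sep = two_component_separation(summary.wgd_score)
print(f"\nhyperploid (>2.5 copies): {summary.hyperploid.mean():.0%}")
print(f"WGD called (score > 0)  : {calls.mean():.0%}")
print(f"call vs simulated truth : {(calls == truth).mean():.0%} agreement")
print(f"score bimodality (two-cluster separation index): {sep:.1f}  (>2 = bimodal)")

# Duplicated genomes sit near +30..+44, unduplicated near -44..-20; the
# separation index far above 2 reflects the same bimodal score distribution
# seen in real allele-specific copy-number cohorts.
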