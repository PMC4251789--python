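"""Simulate a synthetic tumour cohort and inspect its composition.

Draws a mixed cohort — quiet near-diploid (MSI-like) genomes and CNA-rich
(CIN-like) genomes, a fraction of which carry a whole-genome duplication —
with a relative-loss lesion planted at higher frequency in the disseminated
group, then prints what was generated.
"""

from cnascan import SimulationConfig, simulate_cohort

cfg = SimulationConfig(n_disseminated=30, n_control=25, seed=7)
cohort = simulate_cohort(cfg)

t = cohort.truth
print(f"samples: {len(cohort.profiles)} "
      f"({cfg.n_disseminated} disseminated / {cfg.n_control} control)")
print(f"quiet (MSI-like) genomes : {(t.genome_class == 'quiet').sum()}")
print(f"CIN-like genomes         : {(t.genome_class == 'cin').sum()}")
print(f"whole-genome duplicated  : {t.wgd.sum()}")
for grp in ("disseminated", "control"):
    sub = t[t.group == grp]
    print(f"lesion frequency in {grp:13s}: {sub.lesion.mean():.2f}")

p = cohort.profiles[0]
print(f"\nfirst sample {p.sample_id}: {len(p.segments)} segments, e.g.")
for s in p.segments[:4]:
    print("  ", s)

# The lesion frequencies approach the configured 0.50 / 0.15 as the cohort
# grows; each segment line is an allele-specific state such as 2m1 (normal
# heterozygous diploid) or 1m0 (one copy lost, LOH).
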