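"""Hardy-Weinberg structure of a randomly mating diploid guild.

First reproduces a worked example: the expected genotype counts for the
observed alpha-locus counts of a reference 140-agent random-mating run.
Then evolves a 140-agent diploid population and tests its own final
generation for HW proportions using allele lineage tags.
"""

from guildsim import EpochConfig, ReproductionMode, hw_expected_counts, run_epoch
from guildsim.analysis import genotype_counts

# --- worked example: observed counts at a three-allele locus, N = 140
observed = {("a1", "a1"): 22, ("a1", "a2"): 38, ("a2", "a2"): 18,
            ("a2", "a3"): 22, ("a3", "a3"): 14, ("a1", "a3"): 26}
res = hw_expected_counts(observed)
print("worked example (three alleles, N = 140):")
print("allele frequencies:",
      {a: round(f, 3) for a, f in res.frequencies.items()})
for g in sorted(res.observed):
    print(f"  {g[0]}{g[1]}: observed {res.observed[g]:>2}  expected {res.expected[g]:.1f}")
print(f"chi-square = {res.chi2:.2f} on {res.df} df, p = {res.p_value:.3f}"
      " (not significant: the sample is in HW proportions)\n")

# --- a simulated diploid epoch, tested the same way
result = run_epoch(
    EpochConfig(n_agents=140, mode=ReproductionMode.DIPLOID_RANDOM,
                n_generations=60),
    seed=3,
)
counts = genotype_counts(result.final_agents, "alpha")
sim = hw_expected_counts(counts)
print(f"simulated 140-agent diploid run: {len(sim.alleles)} surviving "
      f"alpha alleles, chi-square = {sim.chi2:.2f} on {sim.df} df, "
      f"p = {sim.p_value:.3f}")
print("Random mating and random segregation keep each progeny cohort in",
      "Hardy-Weinberg proportions even while selection shapes the guild.",
      sep="\n")
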