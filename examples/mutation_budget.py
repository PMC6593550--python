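"""Is a dataset deep enough for eForb calls?  A back-of-envelope check.

Converts a per-nucleotide mutation rate into a per-codon missense rate,
then multiplies by the total evolutionary time of a tree to estimate how
many missense mutations each site has 'tested' over the tree.
"""

from evoprob import codon_missense_rate, expected_missense_mutations, tree_span
from evoprob.simulate import vertebrate_fixture

per_site = 2.2e-9  # nucleotide mutations per site per year (vertebrate-like)
rate = codon_missense_rate(per_site, "Standard")
print(f"missense mutation rate per codon per year: {rate:.3g}")

tree = vertebrate_fixture()
total_years = tree_span(tree) * 1e6  # branch durations are in My
n = expected_missense_mutations(rate, total_years)
print(f"tree time: {total_years:.3g} years -> {n:.1f} expected missense "
      "mutations per codon")
# Tens of expected mutations per site mean many alternative amino acids
# have been tried by evolution, so an allele never observed across the
# alignment is genuinely informative (likely evolutionarily forbidden).
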