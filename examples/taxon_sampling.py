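"""How taxon sampling shapes EP estimates.

Temporal sampling adds ever more distant clades to the dataset; the EP
of an allele restricted to the focal clade falls as the sampled
evolutionary time span grows, eventually crossing the eForb threshold.
"""

from evoprob import prune_to
from evoprob.evaluation import temporal_experiment
from evoprob.simulate import SimulationConfig, simulate_alignment, vertebrate_fixture

fx = vertebrate_fixture()
keep = {"human", "chimpanzee", "gorilla", "rhesus", "marmoset", "mouse",
        "dog", "opossum", "chicken", "frog", "zebrafish", "lamprey"}
tree = prune_to(fx, keep)
cfg = SimulationConfig(tree, rate=5e-4, alpha=1.0, p_inv=0.2, n_sites=25, seed=6)
aln, _ = simulate_alignment(cfg)

df = temporal_experiment(aln, tree, focal="human", sites=[1])
human_aa = aln.sequence("human")[0]
traj = df[df.allele == human_aa]
print(f"EP of the human residue ({human_aa}) at site 1 as sampling deepens:")
for _, row in traj.iterrows():
    print(f"  iteration {int(row.iteration):2d}: {int(row.n_taxa):2d} taxa, "
          f"span {row.span:7.1f} My, EP {row.ep:.3f}")
# The span column is the total evolutionary time in the subsampled tree;
# more span means more mutations have been put to the test of selection,
# so eForb calls become more trustworthy.
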