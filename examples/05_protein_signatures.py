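"""Secreted-protein signature of a trait module.

Plants a family of short, cysteine-rich, signal-peptide-bearing proteins
restricted to species-specific orthogroups of one species (the pattern of
nodule cysteine-rich-like peptides), then recovers the signature: signal
peptide enrichment, shorter lengths, higher Cys content, and enrichment
of small Cys-rich proteins in species-specific orthogroups.
"""
import phylorecruit as pr
from phylorecruit import simulate as sim

tree = sim.simulate_tree(9, seed=31)
og, _ = sim.simulate_orthogroups(tree, n_hogs=300, seed=32)
sp = tree.tip_names[0]
proteins, release, og_ext = sim.simulate_proteomes(
    og, {"species": sp, "ncr_like": 60, "release_background": 60}, seed=33
)
ss = pr.classify_species_specific(og_ext)
features = pr.compute_protein_features(proteins, og_ext, set(release.gene_ids), ss)
report = pr.release_signature_tests(features, pr.AnalysisConfig())

print(f"release module: {report['n_release']} proteins; "
      f"background: {report['n_background']}")
print(f"signal-peptide odds ratio: {report['signalp_odds_ratio']:.1f} "
      f"(p = {report['signalp_p']:.3g})")
print(f"mean length release vs background: "
      f"{report['mean_release_length']:.0f} vs {report['mean_background_length']:.0f} aa "
      f"(Welch p = {report['p_length']:.3g})")
print(f"Cys proportion ratio of means: {report['ratio_mean_cys_prop']:.2f} "
      f"(p = {report['p_cys_prop']:.3g})")
print(f"species-specific enrichment among small Cys-rich proteins: "
      f"OR = {report['ss_small_cys_odds_ratio']:.1f} "
      f"(p = {report['ss_small_cys_p']:.3g})")
print("\nLarge odds ratios with small p recover the planted family: short\n"
      "secreted Cys-rich proteins confined to one species' own orthogroups.")
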