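"""Infer a Potts landscape from simulated trajectory snapshots.

Generates the default desk-scale fixture (L = 30 residues, 5 planted
long-range coupled pairs, 8 sequenced rounds of 2000 sequences), fits the
landscape's mean parameters by trajectory-aware moment matching, inverts to
canonical Potts parameters by mean-field DCA, and compares the inferred
residue-residue interaction ranking against the planted truth.

Runtime: several minutes (300 gradient steps over all 435 position pairs).
"""

import evopotts as ep

truth, dataset, model, _ = ep.default_fixture(seed=42)
data = {r: ep.empirical_frequencies(dataset.rounds[r]) for r in dataset.sequenced_rounds}

landscape, fit = ep.infer_landscape(data, model, truth.wildtype)
print(f"optimization: {fit.n_steps} steps, loss {fit.loss_trace[0]:.0f} -> {fit.loss_trace.min():.0f}")

ranked = ep.interaction_scores(landscape).ranked_long_range_pairs()
planted = set(truth.planted_pairs)
print("\ntop 10 inferred long-range interactions (1-based positions):")
for i, j, f in ranked[:10]:
    mark = "  <- planted" if (int(i), int(j)) in planted else ""
    print(f"  {int(i) + 1:>3} - {int(j) + 1:<3}  F = {f:.3e}{mark}")
hits = len(planted & {(int(i), int(j)) for i, j, _ in ranked[:10]})
print(f"\n{hits} of the 5 planted coupled pairs rank in the top 10.")
print(
    "A planted pair in the top ranks means the method extracted a true\n"
    "residue-residue coupling from nothing but per-round sequence samples."
)
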