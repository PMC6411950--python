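"""Which positions and composition features drive the predictions?

Two complementary views: per-(position, residue) enrichment statistics
between positive and negative windows (two-sample-logo style, Bonferroni
over 600 tests), and information-gain ranking of the 480 EAAC features.
On synthetic data both must point at the planted motif.
"""

from kmalpred.dataset import build_windows
from kmalpred.encodings import eaac_matrix
from kmalpred.feature_analysis import information_gain_ranking, two_sample_logo
from kmalpred.records import POSITIVE
from kmalpred.synthetic import SyntheticConfig, generate_proteome

truth = generate_proteome(SyntheticConfig(n_proteins=600, seed=7))
windows, _ = build_windows(truth.proteins, truth.sites)
pos = [w for w in windows if w.label == POSITIVE]
neg = [w for w in windows if w.label != POSITIVE]
print(f"{len(pos)} positive vs {len(neg)} negative windows")

cells = two_sample_logo(pos, neg, alpha=0.05)
print(f"\n{len(cells)} significant (position, residue) cells; strongest ten:")
for c in cells[:10]:
    print(f"  {c.residue} at {c.position:+d}: {c.freq_pos:.3f} vs {c.freq_neg:.3f} "
          f"({c.direction}, adjusted p={c.p_adj:.2e})")

features, names = eaac_matrix(windows)
ranked = information_gain_ranking(features, names,
                                  [w.label for w in windows], top_n=10)
print("\ntop EAAC features by information gain (bits):")
for r in ranked:
    print(f"  {r.rank:2d}. {r.name:10s} {r.information_gain:.4f}  [{r.binning}]")
# The enriched cells reproduce the planted pattern (G at -4..+2, K depleted
# at -1..+2, E around negatives), and the top-gain features are exactly the
# sliding windows covering those offsets - the two views agree.
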