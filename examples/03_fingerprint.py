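"""Compute a full Network Fingerprint on the planted scenario.

One query network is scored against four references (one of which shares
planted nodes and annotation structure with the query).  Each coordinate
is the z-score of the raw similarity against a degree-preserving rewired
null (100 permutations), so values near 0 mean "no more similar than
expected from topology alone".
"""

from netfingerprint import calc_fingerprint, plot_data, top_fraction
from netfingerprint.synthfix import make_refset_scenario

bundle = make_refset_scenario(seed=1)
fp = calc_fingerprint(bundle.query, bundle.refset, bundle.background, nperm=100, seed=1)

print(f"fingerprint of {fp.query_name!r} against {len(fp)} references "
      f"(nperm={fp.nperm}):\n")
print(fp.to_frame().to_string(index=False, float_format=lambda v: f"{v:.4f}"))

print("\ntop quartile (ranked by standardized score):")
for group, name, z in top_fraction(fp, 0.25):
    print(f"  {group}/{name}: z = {z:.3f}")

planted = bundle.ledger.records["related_reference"]
print(f"\nplanted related reference: {planted!r} — a positive z means the observed")
print("functional correspondence exceeds what rewired (degree-matched) nulls give.")
print("unrelated references share no nodes, so their raw and null scores are all 0.")

print("\nplot-ready table (contiguous per-group index blocks):")
print(plot_data(fp).to_string(index=False, float_format=lambda v: f"{v:.3f}"))
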