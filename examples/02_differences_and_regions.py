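"""From uptake tables to response regions: RDU, reporters, 0.5 Da rule.

Uses the built-in Hsp90 N-terminal-domain dataset. Relative deuterium
uptake (RDU = deuterons exchanged / exchangeable amides) ranks peptides as
reporters; apo-vs-bound differences above 0.5 Da mark responding peptides,
which merge into residue-interval response regions.
"""

from hdx_allomap import (
    compute_rdu,
    difference_profile,
    make_hsp90_fixture,
    merge_regions,
    reporter_regions,
)

fx = make_hsp90_fixture()

# Reporter peptides: RDU above half the protein's maximum at the 10 min
# labeling time.
rdu = compute_rdu(fx.apo)
rep = reporter_regions(rdu, short_times=[10.0])
print(f"max RDU {rep.max_rdu:.2f} -> reporter threshold {rep.threshold:.3f}; "
      f"{len(rep.peptide_ids)} of {len(fx.peptides)} peptides are reporters")

# Apo vs radicicol-bound: deltas above 0.5 Da (positive = protection).
profile = difference_profile(fx.apo, fx.bound["radicicol"], threshold_da=0.5)
print(f"{len(profile.significant_peptides)} significant peptides")

regions = merge_regions(profile.significant_peptides)
print("merged response regions (residue spans, max |delta| over exposures):")
for r in regions:
    print(f"  {r.start:>3}-{r.end:<3} {r.direction:<11} {r.magnitude:.2f} Da")
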