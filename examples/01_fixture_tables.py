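"""Inspect the transcribed study tables.

Loads the three published result tables — the eleven putative risk
haplotypes, the five prioritized deleterious variants and the
17-individual carrier/ancestry matrix — and recomputes the arithmetic
and counts they report.
"""

from founderscan.fixtures import load_fixture_tables

tables = load_fixture_tables()

t1 = tables.haplotypes
matches = t1["length_printed_mb"].round(2) == t1["length_computed_mb"].round(2)
print(f"{len(t1)} risk haplotypes; end-start reproduces the printed Mb length "
      f"for {matches.sum()} rows")
print("flagged discrepancies:", ", ".join(t1.loc[t1.length_discrepant, "hap_id"]))

m = tables.carrier_matrix
hap_cols = [c for c in m.columns if c.startswith("hap_")]
n = m[hap_cols].sum(axis=1)
print(f"{(n > 0).sum()} of {len(m)} affected individuals carry a "
      f"variant-bearing haplotype; {(n >= 2).sum()} carry more than one")
print(f"{sum('B' in fp for fp in m.loc[n > 0, 'fp_set'])} of those carriers "
      f"descend from founder pair B "
      f"(of {sum('B' in fp for fp in m['fp_set'])} B descendants in total)")
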