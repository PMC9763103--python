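"""Generate one synthetic replicate of the study design.

Builds the six-founder-pair pedigree, drops founder haplotypes with
recombination, plants a 3.53 Mb risk haplotype (with an embedded
deleterious missense variant) on founder pair B, assigns phenotypes and
draws the two array-genotyped control cohorts.
"""

from founderscan.pipeline import simulate_dataset
from founderscan.simulate import SimulationConfig

config = SimulationConfig(penetrance=1.0, phenocopy_rate=0.0)
ds = simulate_dataset(config, seed=1)

print(f"pedigree: {len(ds.pedigree)} individuals, "
      f"{len(ds.pedigree.sampled_ids)} sampled "
      f"({sum(ds.affected.values())} affected)")
print(f"phased markers: {len(ds.phased_panel.markers)}  "
      f"WGS markers: {len(ds.wgs_genotypes.markers)}")
print(f"controls: {[c.n_samples for c in ds.controls]} individuals "
      f"on {len(ds.controls[0].markers)} array markers")

planted = ds.truth.planted[0]
carriers = ds.truth.carrier_set(planted, ds.phased_panel.samples)
print(f"planted haplotype: chr{planted.chrom}:{planted.start_bp}-{planted.end_bp} "
      f"({planted.length_mb:.2f} Mb, founder pair {planted.founder_pair})")
print(f"truth carriers: {sorted(carriers)}")
# carriers share flanking founder sequence beyond the planted window too
print("truth shared interval (what the pipeline can recover):",
      ds.truth.shared_interval(planted, ds.phased_panel.samples))
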