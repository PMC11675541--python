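"""Simulate a genome with planted retrocopies and recover them.

Builds a 3-contig genome with 20 planted retro events (noiseless copies) and
5 DNA-level duplication controls, runs the identification pipeline, and
scores the calls against the planted truth.
"""

from retrokit import retrocopy_caller as rc
from retrokit import synthetic_data as sd

cfg = sd.SimulationConfig(seed=7, substitution_probability=0.0,
                          frameshift_probability=0.1,
                          premature_stop_probability=0.1,
                          chimeric_probability=0.3,
                          retrogene_probability=0.25)
bundle = sd.generate_bundle(cfg, with_expression=False)
truth = [t for t in bundle.truth if t.kind == "retro"]
print(f"planted {len(truth)} retro events and "
      f"{sum(t.kind == 'dna_dup' for t in bundle.truth)} DNA-duplication controls")

records = rc.call_retrocopies(bundle.genome, bundle.genes)
print(f"called {len(records)} retrocopies\n")
for r in records[:5]:
    print(f"  {r.retro_id}  {r.contig_id}:{r.start}-{r.end}  parent={r.parent_gene_id}"
          f"  class={r.retro_class}  introns_lost={r.introns_lost}")

matched = sum(
    1 for r in records for t in truth
    if t.contig_id == r.contig_id
    and min(t.end, r.end) - max(t.start, r.start) > 0.5 * (t.end - t.start)
)
print(f"\nrecovered {matched}/{len(truth)} planted events "
      f"({len(records) - matched} false positives)")
print("Each record is a genomic locus aligning to an annotated protein with")
print(">=2 of the parent's introns absent - the signature of an mRNA-derived")
print("copy. The DNA-level controls keep their introns and are never called.")

summary = rc.summarize_catalog(records)
print("\ncatalog summary:", summary["class_counts"],
      f"| intact {summary['intact_pct']}%")
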