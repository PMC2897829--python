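"""Generate a small paired tumor/normal cohort and write it in standard formats.

The simulator plants germline CNV loci (shared by tumor and normal), somatic
CNA loci (tumor only) and private CNAs on a regular probe grid, then emits
oracle segmentations with jittered breakpoints plus a redundant toy variant
catalogue.
"""

from collections import Counter

from cnvclass import simulate

fixture = simulate.end_to_end_fixture("small", out_dir="scratch/example_fixture", seed=11)

cohort = fixture.cohort
kinds = Counter(ev.kind for ev in cohort.ground_truth)
print(f"patients:            {len(cohort.patients)}")
print(f"probes per sample:   {cohort.patients[0].tumor.n_probes}")
print(f"planted events:      {kinds['CNV']} germline CNVs, {kinds['CNA']} somatic CNAs")
print(f"DGV records:         {len(fixture.dgv)}")
print(f"files written under: {fixture.directory}")
# Germline events appear in both members of a pair; somatic events only in the
# tumor — that asymmetry is what the truth-labeling stage exploits.
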