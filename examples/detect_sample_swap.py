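"""Detect a reciprocal sample swap in a sequencing batch.

Simulates a batch of 48 samples whose samples 2 and 3 were physically
exchanged before sequencing, writes the sequencing genotypes as a VCF
and the orthogonal assay genotypes as a table, then runs the
verification exactly as one would on real data.
"""

import tempfile
from pathlib import Path

import snptrace as st
from snptrace.profile_io import write_genotype_table

panel = st.load_panel()
spec = st.ScenarioSpec(n=48, seed=11, swaps=[(1, 2)], missing_rate=0.02)
truth, sequencing, orthogonal, ledger = st.generate_cohort(spec, panel)
print("planted swap:", ledger["swaps"])

workdir = Path(tempfile.mkdtemp())
st.write_vcf(sequencing, panel, workdir / "batch.vcf")
write_genotype_table(orthogonal, panel, workdir / "orthogonal.tsv")

seq_profiles = st.extract_from_vcf(workdir / "batch.vcf", panel)
ortho_profiles = st.read_genotype_table(workdir / "orthogonal.tsv", panel)
report = st.verify_assignments(seq_profiles, ortho_profiles, panel)

print(f"confirmed assignments : {len(report.confirmed)}")
print(f"reciprocal swaps      : {report.transpositions}")
for pair, markers in report.informative_markers.items():
    print(f"markers resolving {pair[0]}<->{pair[1]}: {', '.join(markers[:6])} ...")

print(
    "\nEach confirmed sample's exome genotypes matched its own orthogonal "
    "assay within 2 allelic mismatches; the swapped pair matched each "
    "other's assay instead, the signature of a plate transposition."
)
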