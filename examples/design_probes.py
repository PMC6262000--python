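"""Design a rolling-circle FISH probe set for a synthetic transcript.

Tiles a 2 kb transcript with 48 ODNs (30 nt complement + TTTT hinge +
shared 46 nt docking sequence orthogonal to the transcriptome), builds the
barcoded padlock and detection oligo, validates every invariant, and
writes FASTA + TSV outputs.
"""

from pathlib import Path

import numpy as np

import rollfish as rf
from rollfish import io as rfio

rng = np.random.default_rng(2024)
bases = list("ACGT")
transcriptome = {
    "HER2": "".join(rng.choice(bases, size=2000)),
    "GAPDH": "".join(rng.choice(bases, size=1300)),
}

ps = rf.design_probeset(
    "HER2", transcriptome["HER2"], transcriptome, n_odns=48, k=15, seed=1
)
report = rf.validate_probeset(ps, transcriptome)

print(f"ODNs designed : {len(ps.odns)} x {len(ps.odns[0].sequence)} nt "
      "(30 complement + TTTT + 46 docking)")
print(f"padlock       : {len(ps.padlock.sequence)} nt, "
      f"arms {len(ps.padlock.arm_3prime)}/{len(ps.padlock.arm_5prime)}, "
      f"barcode {len(ps.padlock.barcode)} nt")
print(f"complement GC : {ps.report['gc_min']:.2f}-{ps.report['gc_max']:.2f}, "
      f"Tm {ps.report['tm_min']:.1f}-{ps.report['tm_max']:.1f} C")
print("validation    : " + ", ".join(
    f"{k}={'ok' if v else 'FAIL'}" for k, v in report.items()))

out = Path("scratch") if Path("scratch").is_dir() else Path(".")
fasta, tsv = rfio.write_probeset(out / "her2_probeset", ps)
print(f"written       : {fasta} and {tsv}")
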