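"""Marker-level quality control on a simulated cohort.

HWE is tested in controls only; MAF and missingness over all subjects.
A deliberately corrupted marker (no heterozygotes) shows the HWE filter
firing.
"""

import numpy as np

import logicforest as lf

cfg = lf.SimulationConfig(n_subjects=300, n_snps=20, seed=3)
gm, ph, _ = lf.make_study(cfg)

# corrupt one marker: replace heterozygotes by minor-allele homozygotes,
# the signature of a genotyping cluster-calling failure
bad = gm.dosage[:, 5]
bad[bad == 1.0] = 2.0

controls = [s for s, st in zip(ph.subject_ids, ph.status) if st == 0]
filtered, report = lf.apply_qc(gm, controls, hwe_p_min=0.001, maf_min=0.05)

print(report.table[["snp_id", "maf", "hwe_p", "fail_reasons", "retained"]]
      .head(8).to_string(index=False))
print(f"\nretained {filtered.n_snps} of {gm.n_snps} markers")
# snp006 should fail the HWE filter (hwe_p far below 0.001): a marker with
# no heterozygotes cannot arise under random mating at its allele frequency.
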