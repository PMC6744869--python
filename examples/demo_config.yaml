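# Demo pipeline: simulate a wild-type strain and two mutants on the weak
# O3 operator, fit the DNA mutant's binding energy, infer per-condition
# free energies, classify both mutants from their ΔF(c) signatures and
# predict the DNA mutant's profile at a lower copy number.
#
#   simrep run examples/demo_config.yaml

seed: 20
output_dir: simrep_demo_run

design:
  n_replicates: 10
  noise_sd: 0.05

strains:
  wt:
    operator: O3
    r_total: 1220
  mut_dna:
    operator: O3
    r_total: 1220
    mutation: {class: dna, magnitude: 2.0, reference: wt}
  mut_allosteric:
    operator: O3
    r_total: 1220
    mutation: {class: allosteric_full, magnitude: 1.5, reference: wt}

fits:
  - {strain: mut_dna, kind: dna}

classify:
  - {mutant: mut_dna, reference: wt}
  - {mutant: mut_allosteric, reference: wt}

predictions:
  - {posterior: mut_dna, operator: O3, r_total: 260}
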