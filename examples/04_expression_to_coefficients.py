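"""From a (synthetic) post-mortem cohort to conductance coefficients.

Generates a CommonMind-like expression dataset at the published cohort sizes,
filters genes by GWAS minimal SNP p-value (< 5e-6), computes SCZ/HC
group-mean expression ratios per region and maps them to channel
coefficients (the two HVA calcium genes are averaged).  Also shows a
subject-wise coefficient set: one subject's expression normalized to the
healthy-control mean of their region.
"""
from deltacircuit.expression import (build_subject_coefficients, gwas_filter,
                                     population_coefficients_from_dataset)
from deltacircuit.synthetic_data import (GeneratorConfig, generate_expression,
                                         generate_gwas_table)

cfg = GeneratorConfig.default(seed=42, n_decoys=8)
ds = generate_expression(cfg)
print(f"dataset: {ds.counts.shape[0]} genes x {ds.counts.shape[1]} subjects")
table = generate_gwas_table(list(ds.counts.index), cfg)
kept = gwas_filter(list(ds.counts.index), table)
print(f"GWAS filter keeps {len(kept)} genes: {sorted(kept)}")
for region in ("ACC", "PFC"):
    cs = population_coefficients_from_dataset(ds, region, genes=kept)
    pretty = {k: round(v, 3) for k, v in sorted(cs.coefficients.items())}
    print(f"{region} population-averaged coefficients: {pretty}")
subject = ds.subjects("ACC", "SCZ")[0]
cs = build_subject_coefficients(ds, subject)
print(f"subject-wise ({subject}): "
      f"{ {k: round(v, 3) for k, v in sorted(cs.coefficients.items())} }")
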