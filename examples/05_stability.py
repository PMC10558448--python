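"""Imputation stability: projection variance vs imputation stochasticity.

Repeating an imputation and recomputing the distance table with the same
directions and partitions splits the spread of ŵ into a within-table part
(random projections) and a between-table part (imputer randomness).  Mean
imputation is deterministic, so its between-repetition variance is exactly
zero; chained equations redraws values each chain, so its variance is
strictly positive.
"""

import imputequal as iq

truth = iq.generate_numeric(n=500, d_informative=10, class_sep=1.0, seed=20)
mask = iq.induce_mcar(truth, 0.25, seed=21)
incomplete = iq.apply_mask(truth, mask)
dirs = iq.sample_directions(d=10, seed=22)
parts = iq.make_half_partitions(n=500, seed=23)

mean_tables = [
    iq.sw_distance_table(truth, iq.impute_mean(incomplete).completions[0],
                         dirs, parts)
    for _ in range(3)
]
mice = iq.impute_chained_equations(incomplete, m=5, seed=24)
mice_tables = [iq.sw_distance_table(truth, c, dirs, parts)
               for c in mice.completions]

for name, tables in (("mean", mean_tables), ("chained_equations", mice_tables)):
    rep = iq.stability_analysis(tables, threshold=1.0)
    print(f"{name:>18}: within-table var {rep.within_table_variance:.2e}, "
          f"between-repetition var {rep.between_table_variance:.2e}")
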