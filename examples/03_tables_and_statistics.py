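"""Summaries and statistics over the packaged EST tables.

Loads the 347 packaged records, tallies them by transformation class and
template category, and reproduces the abundance–length correlation and the
regional sign tests.
"""

from swingerscan import (
    abundance_length_correlation,
    class_summaries,
    load_table_fixtures,
    sign_test,
    summarize_tables,
)

records = load_table_fixtures()
summary = summarize_tables(records)

print(f"records: {summary.total} "
      f"({summary.symmetric_count} symmetric, "
      f"{summary.asymmetric_count} asymmetric)")
for name, count in sorted(summary.class_counts.items(), key=lambda kv: -kv[1]):
    print(f"  {name}: {count}")
print(f"mitochondrial: {summary.mitochondrial_count} "
      f"(ND2: {summary.mito_gene_counts['nd2']}), "
      f"PABPC1: {summary.gene_counts['PABPC1']}, "
      f"non-coding: {summary.noncoding_count}, "
      f"uncharacterized: {summary.uncharacterized_count}")

summaries = class_summaries(
    [(r.transformation, r.aligned_length, r.percent_identity)
     for r in records])
corr = abundance_length_correlation(summaries)
print(f"\nlog10(abundance) vs mean aligned length over "
      f"{corr.n} classes: r = {corr.r:.2f}, two-tailed P = {corr.p:.4f}")
print("→ more abundant exchange classes also align over longer stretches.")

mito = sign_test(38, 43)
nuclear = sign_test(33, 33)
print(f"\nmid+3' regional bias, mitochondrial: 38/43 "
      f"(one-tailed exact P = {mito.p:.5f})")
print(f"mid+3' regional bias, nuclear:       33/33 "
      f"(one-tailed exact P = {nuclear.p:.3e})")
print("→ hits avoid the 5' third of their genes far beyond the 2/3 the "
      "null predicts.")
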