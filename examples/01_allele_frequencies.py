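"""Stratum-wise GJB2 allele accounting on the bundled reference cohort.

Builds the deaf-by-deaf (DXD) mate cohort and prints the per-variant allele
counts over 2N chromosomes — the accounting behind the headline figure that
roughly half of all DXD-mate chromosomes carry a GJB2 sequence change, and
about a third a pathogenic one.
"""

from dfnb1 import allele_counts, default_registry, make_fixture

registry = default_registry()
cohort = make_fixture("T8", registry)

table = allele_counts(cohort, "dxd-mates", genes=("GJB2",), class_filter="all")
print(table.to_dataframe().to_string(index=False))
print()
pathogenic = allele_counts(cohort, "dxd-mates", class_filter="pathogenic")
print(
    f"All variants: {table.total_count}/{table.denominator} chromosomes "
    f"({table.overall_percent}%); pathogenic incl. novel: "
    f"{pathogenic.total_count}/{pathogenic.denominator} ({pathogenic.overall_percent}%)"
)
print("W24X alone accounts for", table.variant_percent("GJB2", "W24X"), "% of chromosomes.")
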