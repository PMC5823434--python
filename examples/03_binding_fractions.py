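"""Score SPOT-array peptide binding specificity as binding fractions.

Generates synthetic binding matrices for 4 species with planted specific
peptide-domain pairs, converts intensities to binding fractions (each
peptide's share of total family signal), calls specific interactions at
BF > 0.5 and prints one domain's cross-species summary.
"""

from specon import (
    BindingSpec,
    binding_fraction,
    call_specific,
    generate_binding,
    summarize_domain_binding,
)

data = generate_binding(BindingSpec(seed=0, n_peptides=120, n_domains=10))
tables = []
for name, matrix in data.matrices.items():
    table = binding_fraction(matrix)  # merging not needed: already per-domain
    tables.append(table)
    calls = call_specific(table)
    print(f"{name}: {len(table.bf)} peptides retained, "
          f"{len(table.excluded_peptides)} below the 1000-unit filter, "
          f"{len(calls)} specific calls")

domain = data.truth["domain"].iloc[0]
s = summarize_domain_binding(tables, domain)
print(f"\nsummary for {domain}:")
print(f"  specific peptides (BF > 0.5 in >= 1 species): {s.n_specific_peptides}")
print(f"  best peptide {s.best_peptide} with mean BF {s.bf_specific:.2f}, "
      f"specific in {s.n_species_specific}/{s.n_species_with_data} species")
planted = (data.truth["domain"] == domain).sum()
print(f"  planted specific peptides for this domain: {planted}")
print(
    "\nA BF near 1 means the peptide's signal is captured almost entirely by\n"
    "this domain; the species pair shows how reproducible that is."
)
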