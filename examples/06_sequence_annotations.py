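"""Per-ORF sequence annotations: Kozak context, codon optimality, amino-acid
composition, and tissue specificity (Tau)."""

from periscore import pepscore

# Kozak strength of the start-codon context (0-13 additive rule)
for context, plus1 in [("GCCGCC", "G"), ("ACCGCC", "A"), ("TTTTTT", "T")]:
    score = pepscore.kozak_score(context, plus1)
    print(f"Kozak {context}|AUG|{plus1}: {score:>2} / 13")

orf = "ATGGCCCTGAAGTTTTAA"  # ATG GCC CTG AAG TTT + stop
print(f"\noptimal-codon fraction of {orf}: "
      f"{pepscore.optimal_codon_fraction(orf):.2f}")
# GCC/CTG/AAG are in the 17-codon high-usage list; ATG and TTT are not.

peptide = "MALKF"
fractions = pepscore.aa_category_fractions(peptide)
print(f"\naa category fractions of {peptide} (categories overlap):")
for category, value in fractions.items():
    print(f"  {category:<12} {value:.2f}")

expression = [12.0, 0.5, 0.0, 0.2, 0.1]  # one dominant tissue
print(f"\nTau index of {expression}: {pepscore.tau_index(expression):.3f}")
# Tau near 1 marks tissue-restricted expression; 0 would be uniform.
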