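"""Map acute EC50/LC50 concentrations onto EPA aquatic-toxicity categories.

Concentrations (mg/L) come from measurements or external predictors;
the five categories run from practically non-toxic (> 100 mg/L) to very
highly toxic (< 0.1 mg/L).  -log10(concentration) gives a scale where
larger = more toxic.
"""

from algiscore import classify_epa, negative_log_transform

for conc in (150.0, 50.0, 5.0, 0.5, 0.05):
    print(f"EC50 {conc:>7.2f} mg/L -> {classify_epa(conc):<22} "
          f"-log10 = {negative_log_transform(conc):+.2f}")
print("\nA compound that is a strong algicide but 'very highly toxic' to "
      "Daphnia or fish would be a poor candidate for field use.")
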