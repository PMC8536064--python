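{
  "enzyme": "thermolysin",
  "p1_prime_targets": "AFILMV",
  "blocking_rules": [
    {"position": "P2prime", "residues": "P", "note": "no cleavage when the residue after the new N-terminus is proline"},
    {"position": "P1", "residues": "DE", "note": "acidic residue in P1 suppresses cleavage"}
  ],
  "provenance": "Approximation of the ExPASy PeptideCutter thermolysin specificity: cleavage N-terminal to bulky hydrophobic residues (A, F, I, L, M, V) with two context exceptions. The full PeptideCutter exception table is not reproduced; replace this file with a user transcription for exact concordance."
}
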