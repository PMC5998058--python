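"""Translate mRNA transcripts to candidate proteins via six-frame ORF search.

Transcript input is translated with a longest-ORF scan over all six reading
frames before classification; transcripts whose longest ORF is shorter
than 60 aa are rejected.
"""

from fertpred import NucleotideSequence, translate_longest_orf
from fertpred.sequence_io import reverse_complement

CODON = {"A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
         "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "TTA",
         "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
         "S": "TCA", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT"}

# this repeat's other five reading frames are all stop-interrupted, so the
# designed coding region is the unique longest ORF
peptide = "MIHKLRVCWMI" * 8  # 88 aa
cds = "".join(CODON[aa] for aa in peptide)
transcript = NucleotideSequence(id="tx1", bases="ATAA" + cds + "TAAACGT")

protein = translate_longest_orf(transcript)
print(f"transcript {transcript.id}: {len(transcript)} nt")
print(f"longest ORF translation: {len(protein.residues)} aa")
print(f"matches designed peptide: {protein.residues == peptide}")

rc = translate_longest_orf(reverse_complement(transcript))
print(f"reverse-complement strand gives same length: "
      f"{len(rc.residues) == len(protein.residues)}")

short = NucleotideSequence(id="short", bases=cds[:90])
print(f"30-codon transcript below the 60 aa minimum -> {translate_longest_orf(short)}")

print()
print("The translated protein can be passed directly to predict_two_layer;")
print("the CLI does the same with `fertpred predict --type transcript`.")
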