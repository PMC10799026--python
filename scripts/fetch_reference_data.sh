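#!/usr/bin/env bash
# Download the external reference data used by the network-dependent
# acceptance tests (tests/test_acceptance.py criteria 4, 5 and 6).
#
# This script needs internet access; run it from the repository root.
# Tests that depend on these files skip themselves when the files are
# absent, so the offline suite is unaffected either way.
set -euo pipefail

DEST="data/reference"
mkdir -p "$DEST/pdb"

# --- Criterion 6: RefSeq protein records (sequence-derived masses) ---------
# MtGS (Methanothermococcus thermolithotrophicus) and MsGS (Methermicoccus
# shengliensis) glutamine synthetase accessions.
for acc in WP_018154487.1 WP_042685700.1; do
  curl -fsSL \
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=protein&id=${acc}&rettype=fasta&retmode=text" \
    -o "$DEST/${acc}.fasta"
done

# --- Criterion 5: deposited coordinate sets --------------------------------
# 8ool: MtGS apo (TbXo4 form); 8oon: MtGS apo without TbXo4; 4lnn: BsGS apo.
# The remaining entries of the study (optional, not used by tests):
#   8ooo 8ooq 8oow 8oox 8ooz 4lni 4lnk
for code in 8ool 8oon 4lnn; do
  curl -fsSL "https://files.rcsb.org/download/${code}.pdb" \
    -o "$DEST/pdb/${code}.pdb"
done

# --- Criterion 4: curated GSI-alpha family (group counts 8/17 and 6/17) ----
# The published supplementary material (Supplementary Data 1 of
# doi:10.1038/s42003-023-05726-w) provides the 504 GSI-alpha sequences and
# the 17-group delineation, but not in a directly machine-readable layout.
# After downloading it from the journal website, prepare by hand:
#   $DEST/group_alignment.fasta  aligned FASTA of the 17 groups' sequences,
#                                containing the row WP_018154487.1 as the
#                                numbering reference
#   $DEST/groups.tsv             two columns: sequence_id <TAB> group_id,
#                                17 distinct group ids
# (an MSA produced with any standard aligner, e.g. MAFFT/MUSCLE, is fine as
# long as the reference row is present).
echo "Supplementary Data 1 must be prepared manually; see comments above."
echo "Done. Fetched files are in $DEST/."
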