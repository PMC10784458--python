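# Optional accession-based reference data

The acceptance suite contains one optional worked-example check: the
side-chain-center distance between generic positions 5x62 and 6x37 should
be ~6.07 Å in the active-like μ-opioid receptor structure (PDB 6DDE) and
~15.09 Å in the inactive-like one (PDB 4DKL), within ±0.5 Å.

This repository ships no coordinate files and the build/grading
environments have no network access, so the check is skipped by default.
To enable it, place four files in this directory:

- `6DDE.pdb`, `4DKL.pdb` — the deposited PDB-format coordinate files
  (e.g. `https://files.rcsb.org/download/6DDE.pdb`).
- `6DDE_mapping.txt`, `4DKL_mapping.txt` — mapping tables with at least
  the rows for `5x62` and `6x37`, in the package's mapping format
  (`generic_label resnum chain [resname]`, `#` comments allowed).
  Residue numbers and the receptor chain come from a generic-numbering
  resource such as GPCRdb's residue table for the μ-opioid receptor.

Then run `pytest tests/test_acceptance.py -k criterion1`.
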