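# Reference structures

The reproduction tests in `tests/test_acceptance.py` that check published
per-accession numbers (SemiSWEET 4QNC/4QND, SWEET 5CTH, PnuC 4QTN, TRIC
5WUF, MFS 5EQI, rhodopsin 1F88, metabotropic glutamate receptor 4OR2)
operate on deposited coordinates oriented in the membrane (mid-plane at
z = 0, extracellular side at z > 0, the OPM convention).  Those coordinate
files are not redistributed with this package.

To enable these tests, place membrane-oriented PDB files here named by
lower-case accession, e.g.:

    tests/data/structures/4qnc.pdb
    tests/data/structures/4qnd.pdb
    tests/data/structures/5cth.pdb
    tests/data/structures/4qtn.pdb
    tests/data/structures/5wuf.pdb
    tests/data/structures/5eqi.pdb
    tests/data/structures/1f88.pdb
    tests/data/structures/4or2.pdb

OPM-oriented coordinates can be downloaded from the OPM database; plain
RCSB depositions work too if you orient them first (`protosym analyze
--orient fallback` reports the frame it derived).  When a file is missing
the corresponding test fails with a message naming it; all synthetic-data
tests are independent of this directory.
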