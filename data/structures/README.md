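# Reference structure inputs

The published-geometry acceptance tests (`tests/test_acceptance.py`) and the
optional reference-structure section of `scripts/acceptance.py` consume
experimental coordinates from this directory. These files are **not bundled**
(they are third-party deposited data and require network access to retrieve);
without them the corresponding tests report failure and the acceptance script
simply omits the reference-structure quantities.

To provide them:

```sh
# CcdB crystal structure (dimer)
curl -o 3vub.pdb https://files.rcsb.org/download/3VUB.pdb
# DgkA X-ray structure
curl -o 3ze5.pdb https://files.rcsb.org/download/3ZE5.pdb
# DgkA NMR ensemble (16 poses)
curl -o 2kdc.pdb https://files.rcsb.org/download/2KDC.pdb
```

The deposited CcdB decoy set (10,659 models, doi:10.5061/dryad.3g092) goes
into `ccdb_decoys/` as individual PDB files.
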