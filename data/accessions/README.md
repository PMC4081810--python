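# Published accession data (not redistributed)

The regression test `tests/test_acceptance.py::test_published_sequence_regression`
replays the two-locus mtDNA analysis on the deposited hummingbird sequences
(GenBank KJ710519–KJ710624). Those records are public but are not bundled
here; fetch them on a machine with network access:

```sh
# ND2 (350 bp) and ATPase 6–8 (727 bp) for the 25 Doricha eliza samples
python - <<'PY'
from Bio import Entrez, SeqIO
Entrez.email = "you@example.org"
ids = [f"KJ{n}" for n in range(710519, 710625)]
h = Entrez.efetch(db="nucleotide", id=",".join(ids), rettype="fasta", retmode="text")
SeqIO.write(SeqIO.parse(h, "fasta"), "all_accessions.fasta", "fasta")
PY
```

Then split the records by locus into aligned FASTA files and add sample
metadata:

- `nd2.fasta` — the 25 ND2 sequences, aligned, 350 bp
- `atpase.fasta` — the 25 ATPase 6–8 sequences, aligned, 727 bp,
  same sample ids as `nd2.fasta`
- `samples.tsv` — tab-separated `sample_id`, `population`
  (`Veracruz` or `Yucatan`)

With the files in place the regression runs automatically as part of the
test suite and checks haplotype counts, diversity, neutrality statistics
and the AMOVA fixation index against the published values.
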