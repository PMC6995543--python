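# earlyfold

Tools for asking whether the *final* fuzzy-oil-drop status of a protein
fragment is already encoded in its *early-stage* backbone conformation.

`earlyfold` implements three connected analyses for protein domain
structures (PDB format, backbone atoms N/CA/C):

1. **Early-stage structural alphabet.** Every residue's Ramachandran point
   (Φ, Ψ) is projected onto an elliptical path (the conformation expected
   when only backbone/peptide-bond preferences act), summarized by the
   parametric angle *t* measured clockwise from an anchor in the
   lower-right quadrant, and discretized into one of seven structural
   codes by fixed integer intervals of *t*:

   | code | A | B | C | D | E | F | G |
   |------|---|---|---|---|---|---|---|
   | t from | 0 | 51 | 86 | 111 | 151 | 194 | 226 |
   | t to   | 50 | 85 | 110 | 150 | 193 | 225 | 359 |

   The elliptical path itself can be re-derived from any corpus: the
   five-residue radius of curvature obeys ln R = aV² + bV + c in the
   aperture angle V between adjacent peptide-bond planes, and the (Φ, Ψ)
   points of fragments on that idealized relationship are fitted with an
   algebraic ellipse.

2. **Fuzzy-oil-drop (FOD) compliance.** A domain's observed hydrophobicity
   density O (pairwise contacts within 9 Å, Levitt sigmoid kernel) is
   compared to the centric 3D Gaussian T and the uniform reference
   R = 1/N through Kullback–Leibler divergences:

       RD = D(O‖T) / ( D(O‖T) + D(O‖R) )

   RD < 0.5 means compliant (a centric hydrophobic core). Noncompliant
   domains are trimmed one worst residue (largest |T−O|) at a time until
   RD < 0.5; removed positions are labelled noncompliant, and runs of at
   least four equal labels feed the window corpora.

3. **Tetrapeptide screen.** A 4-residue window slides along every chain,
   yielding (sequence 4-mer, code 4-mer) pairs collected into two
   contingency tables — 160,000 sequence columns × 2,401 code rows — for
   the compliant and noncompliant corpora (the smaller table is scaled up
   by the size ratio). For each column (and each row) the Pearson
   correlation r between the two tables is tested with
   z = r·√(n−2)/√(1−r²) against the two-sided large-sample critical value
   1.96 (α = 0.05). Tetrapeptides with a *significantly negative* r adopt
   opposite early-stage structural forms in the two corpora — the signal
   of interest.

A first-class synthetic-data module generates torsion samples, ideal
backbones, planted hydrophobic cores and paired corpora with planted
code-frequency contrasts, so the whole stack is testable without any
structure database.

## Worked example

Plant three tetrapeptides whose code-frequency profiles are rank-reversed
between the two classes, rebuild the tables, and screen:

```python
from earlyfold.synthetic_data import make_planted_corpus, PlantedCorpusSpec
from earlyfold.pipeline import tables_from_corpus
from earlyfold.contingency import correlation_screen, negative_significant, scale_smaller

corpus = make_planted_corpus(PlantedCorpusSpec(seed=42))
tc, tn = tables_from_corpus(corpus)
sc, sn, factor = scale_smaller(tc, tn)
print(f"windows: compliant={tc.total:.0f}  noncompliant={tn.total:.0f}  scale factor={factor:.1f}")
for rec in negative_significant(correlation_screen(sc, sn, mode="columns")):
    print(f"{rec.key}  r={rec.r:+.3f}  z={rec.z_stat:+.2f}  n={rec.n}")
```

prints

```
windows: compliant=64000  noncompliant=16000  scale factor=4.0
DKAG  r=-0.152  z=-7.53  n=2401
FVRL  r=-0.142  z=-7.04  n=2401
LFDD  r=-0.146  z=-7.24  n=2401
```

Exactly the three planted sequences (`DKAG`, `FVRL`, `LFDD`) come out
significantly negative: their code-4-mer frequency vectors are
anti-ordered between the compliant and noncompliant corpora, while the 50
null tetrapeptides correlate positively. The same screen in row mode
(fixed code 4-mer across all 160,000 sequences) finds no negatives — the
contrast lives in the sequences, not in the structural forms themselves.

The command line mirrors the library:

```sh
earlyfold simulate backbone --n 60 --seed 1 --out chain.pdb
earlyfold encode chain.pdb --out chain.codes.tsv
earlyfold fod chain.pdb --trim
earlyfold run --ranges ranges.tsv --out run1/
```

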