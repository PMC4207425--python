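# epimatch

Antibody-specific prediction of conformational B-cell epitopes, and
rescoring of rigid-body docking decoys with the predicted epitopes.

Most epitope predictors annotate generically immunogenic regions of an
antigen. `epimatch` instead answers the question an antibody engineer
actually asks: *given this antibody, where on this antigen does it bind?*
It combines a geometric matching of the antigen surface against the
antibody binding site (the CDRs) with a knowledge-based, asymmetric
amino-acid pair score, and then uses the predicted epitope regions to
re-rank the output of global rigid-body docking so that close-to-native
poses rise to the top.

## Method

**Patch enumeration.** Surface antigen residues (relative solvent
accessibility > 7%, Shrake–Rupley) each seed a candidate epitope patch,
grown by two rounds of neighbourhood expansion over surface residues within
4.5 Å (heavy-atom minimum distance).

**Geometric matching.** For a patch *Epi* and binding site *Ab*, every pair
(r_ab, r_ag) ∈ Ab × Epi is a candidate inter-molecular contact — a node of
a graph *G*. Two contacts can coexist in a rigid match only if the
intramolecular Cα distance between the two antibody residues and the one
between the two antigen residues agree to within 1 Å; such pairs are
connected by an edge. For example, contacts with intramolecular distances
of 9.4 Å (antibody side) and 10.2 Å (antigen side) are compatible
(|Δ| = 0.8 Å < 1 Å), while 17.5 Å against 10.2 Å cannot be satisfied
simultaneously.

**Scoring.** With d(n) the degree of node n and PS the Precision Score,

    Score(Epi) = Σ_n d(n) · PS(T_ab(n), T_ag(n))

i.e. each candidate contact is weighted by the number of other contacts it
can satisfy simultaneously and by the likelihood that a contact between its
amino-acid types is docking-correct. Patches are ranked by score and the
top three mutually non-overlapping ones (> 30% shared residues discards the
lower-scoring patch) are reported.

**Precision Score.** PS(T_ab, T_ag) is the estimated probability that a
docking contact between antibody type T_ab and antigen type T_ag is
native-correct. It is estimated from decoy sets of training complexes by
tallying how often each observed contact pair (by residue identity)
reproduces a native contact, with a Laplace pseudocount. The matrix is
asymmetric: PS(G, S) ≠ PS(S, G). The package estimates matrices from its
own synthetic training generator; it does not ship a matrix derived from
real docking runs.

**Decoy rescoring.** Each of the top-N docking decoys (N = 30 for
ZDOCK-style lists, 20 for ClusPro-style) is scored against each predicted
epitope by summing PS over all (binding-site, epitope) residue pairs within
4.5 Å in that pose; the pose keeps the best of its per-epitope scores and
the list is reordered. Decoy quality is judged by CAPRI-style interface
RMSD (Kabsch superposition of the native-defined 10 Å interface regions);
a decoy with I_rmsd < 10 Å is close-to-native.

## Worked example

Generate a toy complex with a planted 6-residue epitope, predict, and
rescore its decoy set (3 near-native + 7 far poses):

```sh
epimatch make-fixtures --outdir fx --n-antigen 40 --n-antibody 8 \
    --epitope-size 6 --seed 1
epimatch predict --antibody fx/native.pdb --antibody-chains H \
    --antigen fx/native.pdb --antigen-chains A --cdr fx/cdr.txt \
    --ps-matrix ps.tsv --outdir pred
```

    antigen: 40 residues, 40 on surface
    epitope 1: seed A2, 14 residues, score 554
    epitope 2: seed A39, 14 residues, score 554
    epitope 3: seed A19, 13 residues, score 406

(`ps.tsv` here was estimated from the synthetic training generator; see
`epimatch estimate-ps --help`.) Evaluating against the planted truth:

```sh
epimatch evaluate --prediction pred/epitopes.json --native fx/native.pdb \
    --antibody-chains H --antigen-chains A --output metrics.tsv
```

    rank  precision_pct  recall_pct  mcc
    1     42.9           100.0       0.57
    2     0.0            0.0         -0.31
    3     23.1           50.0        0.16

The top-ranked patch covers the whole planted epitope (recall 100%) plus
surrounding surface residues (precision 43%) — the method predicts epitope
*regions*, not residue-exact sets. Rescoring the decoys:

```sh
epimatch rescore --decoys fx/decoys.pdb --antibody-chains H \
    --antigen-chains A --cdr fx/cdr.txt --epitopes pred/epitopes.json \
    --ps-matrix ps.tsv --output rescored.tsv
```

    new_rank  source_rank  score  best_epitope
    1         3            3      1
    2         6            3      1
    3         2            2.5    1
    4         1            0      1

The three near-native decoys (source ranks 3, 6, 2) move to the top of the
list; far poses score 0 because they touch none of the predicted epitopes.

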