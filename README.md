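# agaclust

Aminoglycoside antibiotics (AGAs) bind the ribosomal decoding site and make
the ribosome misread mRNA. Quantitative proteomics of AGA-treated *E. coli*
shows that, besides single amino-acid substitutions, bactericidal AGAs
produce *clusters* of substitutions within one tryptic peptide, orders of
magnitude more often than independent errors would allow — because a drug
molecule can stay bound across several elongation cycles and keep the
ribosome error-prone. `agaclust` implements this picture as a tested,
generative pipeline for people who study translation fidelity with
peptide-level mass spectrometry:

- a **two-state Markov model of elongation** (drug bound / unbound per
  codon) with per-codon binding probability β, per-translocation retention
  probability q, and bound-state misreading probability m·w, emitting
  synthetic MS-like intensity tables across drug titrations, time courses
  and solubility fractions (plus an error-prone *ram*-strain mode with
  independent errors);
- the **error-frequency statistics** used to quantify mistranslation from
  such tables: E_f (missense/parent intensity ratio with median-fallback
  parents), the cluster frequency E_f^cluster, the stochastic expectation
  ∏E_f, the amplification A = E_f^cluster/(E_f^1st·E_f^2nd), three
  estimators of the conditional next-error frequency E_f^next (with
  E_f^1st·E_f^next = E_f^cluster), and the distance profile of E_f^next
  with an exponential fit N(d) = c·q^d that recovers the retention
  probability;
- the **genetic-code layer**: near-cognate (single-mismatch) enumeration,
  3rd > 1st > 2nd mismatch-position classification, in-silico tryptic
  digestion with cleavage-change detection, and cluster-candidate
  prediction from measured single-error frequencies;
- the **proteotoxicity normalizations**: aggregation enrichment over the
  correct-peptide cohort, thermostability curves, and proteome-table
  preprocessing (presence filter, down-shifted normal imputation, 0–1
  interval scaling).

The model's key observable: two errors separated by d correct residues
require the drug to survive d + 1 translocations, so the conditional
next-error frequency decays as

    E_f^next(d) = m·w · q^(d+1)

Distance-flat profiles (q ≈ 1, streptomycin-like, "group I") and steeply
decaying profiles with high local E_f^next (q ≈ 0.5, apramycin-like,
"group II") fall out of the same two parameters.

## Worked example

Simulate an apramycin titration of the d = 1 benchmark cluster
(E242D–E244D geometry) and estimate E_f^next:

```python
import agaclust as ag

protein = ag.make_model_protein()
cluster = ag.model_cluster(protein, "E242D-E244D")
config = ag.SimConfig(n_ribosomes=1e8, seed=1)
table = ag.titrate_cluster(protein, cluster, ag.get_preset("Apr"), config)

for conc in (1.0, 4.0, 16.0):
    st = ag.cluster_stat(table, cluster.label, {"concentration_um": conc})
    print(f"{conc:5.1f} uM  E_f^1st={st.ef_first:.3g}  E_f^cluster={st.ef_cluster:.3g}  "
          f"E_f^next={st.efnext:.3f}  amplification={st.amplification:.0f}")

efnext, _ = ag.efnext_from_titration(table, cluster.label, estimator="ratio")
print(f"median E_f^next across the titration: {efnext:.3f}")
```

prints

```
  1.0 uM  E_f^1st=0.000102  E_f^cluster=2.53e-05  E_f^next=0.247  amplification=3170
  4.0 uM  E_f^1st=0.00038  E_f^cluster=9.95e-05  E_f^next=0.262  amplification=895
 16.0 uM  E_f^1st=0.00161  E_f^cluster=0.000392  E_f^next=0.244  amplification=198
median E_f^next across the titration: 0.247
```

The first-error frequency rises ~16-fold with concentration while
E_f^next stays at the apramycin preset (0.25): the downstream errors are a
property of the drug-bound ribosome, not of the drug dose. The cluster is
hundreds to thousands of times more frequent than the stochastic product
of its single errors (the amplification column).

The same operations are available from a shell:

```sh
agaclust presets
agaclust simulate --protein p.fasta --aga Apr --cluster 242:D,244:D --seed 1 --out table.tsv
agaclust efnext --table table.tsv --cluster E242D+E244D --estimator ratio
agaclust distance-fit --records efnext_by_cluster.tsv --reference Str --seed 0
```

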