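# kinnet

Residue interaction network analysis of protein–kinase inhibitor complexes.

Drug-resistance mutations in kinases such as ABL cluster at residues that
mediate global communication in the protein structure, not merely at atoms
that touch the drug. `kinnet` implements the computational framework that
makes this connection quantitative, for structural bioinformaticians who
want to relate inhibitor binding to network topology:

* **ensemble dynamics** — superposition, computed B-factors
  (B = 8π²/3 · ⟨Δr²⟩), essential-dynamics PCA with mobility profiles over
  the three largest-variance modes, residue cross-correlations C_ij, and
  anisotropic-network-model (ANM) normal modes;
* **contacts and surfaces** — LPC-style 8-class atom typing,
  side-chain contact counts at 4.5 Å, Shrake–Rupley SASA and relative
  solvent accessibility (RSA);
* **residue interaction networks** — edges where the normalized
  interaction strength I_ij = n_ij/√(N_i·N_j) × 100 exceeds I_min = 3.0 %,
  weighted by w_ij = −log|C_ij|, with normalized betweenness centrality
  C_b(i) = Σ_{j<k} g_jk(i)/g_jk / [(N−1)(N−2)/2] from Floyd–Warshall
  all-pairs shortest paths, and apo→holo centrality changes ΔC_b that
  quantify ligand-induced network bridging;
* **MM-GBSA energetics** — ΔG_bind = ⟨ΔG_MM⟩ + ⟨ΔG_solv⟩ − TΔS over a
  single-trajectory ensemble, with σ·SASA nonpolar solvation
  (σ = 0.0072 kcal/(mol·Å²)), pairwise generalized-Born electrostatics and
  rigid-rotor/harmonic-oscillator entropies, plus computational alanine
  scanning (side chain truncated beyond Cβ, Cγ→H, the new hydrogen relaxed
  by ≤1000 steps of steepest descent, entropy omitted);
* **coevolution** — column-pair mutual information MI(i,j) in nats,
  permutation z-scores with the 6.5 significance threshold,
  Kullback–Leibler conservation against background amino-acid frequencies,
  cumulative MI (cMI) and structure-mapped proximity MI (pMI, 5 Å).

Everything runs on synthetic, seed-deterministic inputs generated by the
`synthetic_data` module (toy peptides, elastic-network ensembles, MSAs
with planted conservation/coevolution, and apo/holo complexes whose ligand
bridges two weakly connected lobes), so the full stack is testable without
downloads. Real PDB structures and FASTA/Stockholm alignments are read
through the same interfaces.

## Worked example

```python
from kinnet import synthetic_data as sd, resnet, energetics as en

# apo/holo pair: two network lobes, ligand bridging the lobe tips
apo, holo = sd.gen_complex(sd.ComplexSpec(seed=1))
norm = resnet.normalization_factors([apo])
cb_apo = resnet.betweenness(resnet.build_graph(apo, norm=norm))
cb_holo = resnet.betweenness(resnet.build_graph(holo, norm=norm))
delta = resnet.delta_centrality(cb_apo, cb_holo)
print(delta.sort_values(ascending=False).head(4).round(3))

ens = sd.gen_ensemble(holo, 10, [(6, 0.3)], seed=2)
bfe = en.mmgbsa(ens)
print(f"dG_bind = {bfe.dg_bind:.3f} kcal/mol "
      f"(dG_MM {bfe.dg_mm:.3f}, dG_solv {bfe.dg_solv:.3f})")
print(en.alanine_scan(ens, ["A:1", "A:12", "A:6"]).table.round(3))
```

prints

```
A:1     0.227
A:12    0.227
A:10    0.045
A:3     0.045
Name: delta_betweenness, dtype: float64
dG_bind = -1.350 kcal/mol (dG_MM -0.677, dG_solv -0.673)
           ddG  ddE_vdw  ddE_elec  ddG_np  ddG_gb
residue                                          
A:1      0.394    0.143       0.0   0.250   0.0
A:12     0.315    0.130       0.0   0.185   0.0
A:6      0.001    0.001       0.0  -0.000   0.0
```

The two pocket residues (A:1 and A:12, the lobe tips the ligand bridges)
gain the most betweenness centrality when the ligand binds (ΔC_b = +0.227
each) — the ligand creates a network shortcut that routes inter-lobe
shortest paths through them. The same two residues are the alanine-scan
hot spots (ΔΔG ≈ +0.39 and +0.32 kcal/mol: truncating their side chain
costs binding free energy), while the distal residue A:6 is energetically
silent. High-centrality residues and binding hot spots coincide — the
central observation this framework is built to expose.

## Command line

```sh
kinnet run --outdir out --seed 1          # full synthetic demo
kinnet network --config my.yaml           # single stage (plus dependencies)
```

A YAML config mirrors every flag; outputs are TSV/JSON keyed by
`chain:seq_id` and stamped with the config hash and seed. Re-running the
same config and seed reproduces byte-identical files.

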