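# allodyn

Analysis of protein molecular-dynamics trajectories aimed at one question:
**how do remote regions of a protein communicate?**  The package was built
for studies of allosterically regulated kinase domains — where a
juxtamembrane segment and an activation loop, tens of Å apart, coordinate
through internal dynamics — but every stage operates on generic
multi-frame coordinates plus a topology.

It is a library for Python users: import the stages you need, or run the
`pipeline` facade; the `examples/` directory holds one short narrative
script per capability.

## What it computes

* **Geometry monitors** — best-fit RMSD time series, per-residue RMSF on
  the C/N backbone atoms, center-of-mass distances and angles between
  named segments, and the residue matrix of time-averaged smallest
  heavy-atom distances.
* **Conformational clustering with a convergence criterion.**  References
  are drawn at random and every conformation within RMSD *r* is removed,
  until none remain; all frames are then assigned to their nearest
  reference.  A reference is *lone* if only one trajectory half populates
  its cluster, and over `N_runs` repeats

      c = 1 − ⟨N_lone / N_total⟩,   c ∈ [0, 1],

  with c = 1 meaning every representative conformation is visited in both
  halves (converged sampling).  The same clustering, applied to a segment
  (e.g. an activation loop) across several concatenated models, tabulates
  which conformational families are shared or model-exclusive.
* **Structure annotation** — geometric H-bonds (D···A ≤ 3.5 Å,
  D–H···A ≥ 120°, both inclusive) with per-interaction time occupancy, and
  DSSP-style secondary structure from Kabsch–Sander H-bond energies,
  reduced to 3₁₀-helix / α-helix / β / turn / coil occupancy profiles.
* **Essential dynamics.**  PCA of the superposed coordinate fluctuations;
  the number of modes covering 80 % of the fluctuation; per-atom
  contributions α_i with Σα_i² = 1 over a domain D; the degree of
  collectivity of D in mode m,

      k = (1/n) · exp(−Σ_i α_i² ln α_i²) ∈ [1/n, 1],

  optionally weighted by the mode share λ_m/Σλ; a domain's percentage of a
  mode's global motion; and the norm of a domain's resultant motion.
* **Communication networks.**  Local Feature Analysis turns the retained
  PCA modes into residue–residue residual correlations P(i,j); a threshold
  P_cut is calibrated so ~1.0–1.2 % of cross-correlations exceed it, and
  greedy kernel sparsification yields seed residues whose clusters are
  *independent dynamic segments* (IDSs).  The *commute time*
  CT(i,j) = Var[d(Cα_i, Cα_j)] measures communication efficiency; CT_cut
  is fixed or calibrated so the best-connected residue reaches ~20 % of
  residues.  *Communication pathways* are residue chains whose adjacent
  members share persistent non-bonded contacts (≤ 3.9 Å in ≥ 50 % of
  frames, sequence separation ≥ 2) and whose members are pairwise fast
  (CT ≤ CT_cut); they are classified short/intermediate/long (2–3 / 4–5 /
  >5 residues) and local/extended (end-to-end < / ≥ 10 Å), and residues on
  pathways reaching >10 % of the protein are *hubs*.  Graphs export to
  GraphML/TSV.
* **Synthetic data.**  Generators plant every statistical feature the
  stages are meant to detect — correlated residue blocks, stiff
  low-distance-variance fibers, two-basin ensembles with controllable
  half-mixing, toggling H-bond geometries, ideal helices and a β-hairpin —
  so the whole pipeline is validated end-to-end without MD output.

## Worked example

`python examples/04_communication_network.py` runs the network stage on the
canonical planted system (150 residues, 1000 frames; two concerted blocks,
three mobile loops, one stiff 6-residue fiber) and prints:

```
LFA: 51 modes, P_cut = 0.724 (1.10% of cross-correlations above)
planted blocks: [(24, 34), (48, 58)]
  best-matching IDS S32: residues 24-34 (seed 29)
  best-matching IDS S33: residues 48-58 (seed 50)

CT_cut (calibrated) = 0.114 Å^2, 7 pathways grown
planted fiber [94, 98, 102, 106, 110, 114] recovered as a long/extended pathway (6 residues, end-to-end 31.5 Å)
hubs (connected to >10% of residues through pathways): []
```

Reading this: the P_cut calibration landed inside its 1.0–1.2 % band; both
planted blocks were recovered exactly as independent dynamic segments; the
commute-time threshold was calibrated from the data; and the planted fiber
emerged as a long (6 residues) extended (31.5 Å end-to-end) communication
pathway.  No residue reaches more than 10 % of the chain through pathways,
so there are no hubs in this small system.

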