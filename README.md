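# allonet — structure-based allosteric network analysis

Allostery — a perturbation at one site of a protein changing the behaviour of
a distal site — underlies signalling, enzyme regulation, and a growing class
of allosteric drugs.  `allonet` predicts allosteric coupling directly from a
single 3D structure, with no molecular-dynamics simulation: it converts the
structure into a residue-level contact network, turns contact density into
perturbation-transmission probabilities, and measures coupling by repeated
stochastic propagation.  It is aimed at structural biologists and protein
engineers who want candidate allosteric sites, communication pathways, and
critical residues from nothing but a PDB file.

## The model

From the heavy-atom coordinates, the atom-contact count between residues
*i* and *j* is

    C_ij = Σ_{a∈i, b∈j} H(r₀ − |r_a − r_b|),        r₀ = 3.4 Å

where backbone–backbone atom pairs of sequence-adjacent residues are
excluded (otherwise signal floods trivially along the backbone).  Dividing
by residue size gives the per-atom averaged contacts N_ij = C_ij / C_i
(asymmetric), which map to transmission probabilities

    P_ij = 1 − exp(−α · N_ij),        α = 3.0 by default.

Rows of P are deliberately not normalised: a perturbed residue may excite
several neighbours, or none — the process is a percolation, not a Markov
chain.  One round perturbs a chosen source site and propagates breadth-first:
each newly reached residue receives a single Bernoulli trial from the first
perturbed residue to arrive.  Over 10⁴ rounds, the **allosteric coupling
intensity** (ACI) of a residue is the fraction of rounds in which it was
perturbed.  On top of ACI the package builds:

* **hotspots** — clusters formed by following ACI-ascending pointers on the
  4.5 Å spatial neighbour graph; cluster centers are predicted allosteric
  sites, scored by TPR/PPV against a known site;
* **pathways** — per-round transmission chains from a source site to a
  target site, aggregated into weighted distinct routes;
* **residue importance** — the probabilistic union p_a = 1 − Π(1 − p_i) of
  the weights of all pathways through residue *a*;
* **all-pairs coupling maps** — one propagation run per source residue,
  comparable to NMR chemical-shift covariance analysis (CHESCA) via combined
  chemical shifts CCS = δH + 0.15·δN, absolute Pearson correlation, optional
  Gaussian filtering, and a top-k true-positive rate.

## Worked example

```python
import allonet as an
import numpy as np

pdb_text = an.make_two_domain(6, 4)          # two domains + 4-residue linker
model = an.read_structure(pdb_text)
contacts, avg, probs = an.build_propagation_matrix(model)

cfg = an.PropagationConfig(source=(0,), n_rounds=10_000, seed=42)
profile = an.compute_aci(probs, cfg)
print("ACI of linker residues 7-10:", np.round(profile.aci[6:10], 3))

ens = an.sample_pathways(probs, [0], [15], cfg)
print("top pathway:", "-".join(model.labels()[i] for i in ens.pathways[0].nodes),
      "weight", ens.pathways[0].weight)

dist = an.residue_distance_matrix(model)
hs = an.detect_hotspots(profile, dist)
ev = an.evaluate_sites(hs, list(range(12, 16)), dist)
print("hotspots:", hs.n_hotspots, "| TPR:", ev.tpr, "| PPV:", ev.ppv)
```

prints

```
ACI of linker residues 7-10: [0.987 0.978 0.967 0.957]
top pathway: A/1-A/2-A/4-A/6-A/7-A/8-A/9-A/10-A/11-A/12-A/14-A/16 weight 0.9181
hotspots: 1 | TPR: 1.0 | PPV: 1.0
```

The coupling decays monotonically along the linker (it is the unique route
between the domains), the dominant sampled pathway traverses every linker
residue, and the single predicted hotspot sits in the far domain, fully
recovering the designated site (TPR = PPV = 1).

The same workflows are available from the shell:

```sh
allonet fixtures --kind two_domain --n 6 --out twodom.pdb
allonet aci      --pdb twodom.pdb --active A/1 --seed 42 --out run/
allonet pathways --pdb twodom.pdb --allosteric A/1 --active A/16 --out run/
allonet correlate --pdb twodom.pdb --out run/
```

Each run writes CSV/TSV/JSON results, a B-factor-encoded PDB for structure
viewers, and a `manifest.json` from which the run is exactly reproducible.

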