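# phylopower

Phylogenetic comparative analysis of intersexual power in primates.

Across primate societies, power between the sexes may be male-biased (MP),
co-dominant, or female-biased. Two broad mechanisms could shape which
pattern a species exhibits: *dominance* (asymmetry in fighting ability,
proxied by male-biased sexual dimorphism) and *leverage* (asymmetry in the
mating market, proxied by group sex ratio and estrous synchrony).
`phylopower` implements the full comparative workflow for testing these
hypotheses and projecting them onto a dated phylogeny, for researchers in
primatology and comparative behavioral ecology:

1. **Phylogenetic logistic regression** of the binary power label
   (MP = 1) on one standardized predictor at a time — body mass ratio
   (BMR, male/female), canine ratio (CR), expected estrous overlap (EO, %)
   or sex ratio (SR, males per female) — with the residual correlation
   among species following the phylogeny:

   P(MP | x) = logistic(b₀ + b₁·x),  working correlation
   R(λ) = (1−λ)·I + λ·corr(V),

   where V is the phylogenetic variance–covariance matrix and λ ∈ [0, 1]
   the phylogenetic-signal parameter. Inference is by parametric bootstrap
   (default 2000 replicates): the binary trait is re-simulated up the tree
   under the fitted model and refit, giving coefficient means, percentile
   and basic intervals, bias-corrected estimates, and two-sided p-values.
2. **Discrete ancestral-state reconstruction** of the 3-state power
   category under an Mk model (equal-rates default) with Felsenstein
   pruning, reporting per-node scaled likelihoods that sum to one.
3. **Continuous ancestral-state reconstruction** of log₁₀ BMR/CR/SR:
   six evolutionary models (BM, λ, κ, δ, Ornstein–Uhlenbeck, early-burst)
   fitted by ML; models beating BM by likelihood-ratio test compete on
   AIC and the winner rescales the tree; node MLEs and 95% CIs come from
   the exact Gaussian conditional distribution given the tips.
4. **Ancestral power prediction**: reconstructed ratio-scale node values m
   map through the fitted coefficients to odds = exp(b₀ + log₁₀(m)·b₁)
   and probability = odds/(1+odds), assembling a per-clade table
   (ten named clades from crown Primates to Hominoidea).

Trees are dated (branch lengths in My), read and written as Newick, with
pruning, fossil grafting (divergence-date placement plus a one-million-year
buffer rule) and branch-length transforms built in. A synthetic-data module
generates clade-structured fixtures with the same statistical anatomy as
the real study sample, so the whole pipeline is testable offline.

## Worked example

```python
import numpy as np
import phylopower as pp

# a 79-species clade-structured fixture (tree, trait table, named clades)
tree, table, clades = pp.make_fixture(pp.SimulationConfig(seed=0))

# regression of power on body-mass dimorphism
y = (table.frame["power"] == "MD").astype(float).to_numpy()
z, std = pp.log10_standardize(table.frame["bmr"].to_numpy())
labels, V = pp.vcv_matrix(tree)
fit = pp.fit_phylogistic(y, z, V)
boot = pp.parametric_bootstrap(fit, tree, z, reps=200, seed=42)
print(f"b1 = {fit.b1:.3f}, signal = {fit.signal:.2f}, "
      f"bootstrap p = {boot.p_b1:.4f}")
# b1 = 1.660, signal = 0.31, bootstrap p = 0.0000

# predicted probability of male-biased power at an ancestral BMR of 1.14
print(round(pp.probability_at(0.2134, 1.6228, 1.14), 2))
# 0.58
```

The first line says dimorphism raises the odds of male-biased power
(positive slope, ~1.7 log-odds per SD of log₁₀ BMR) with moderate
phylogenetic signal, and the bootstrap rejects a zero slope. The second
evaluates the fitted predictive equation at a reconstructed ancestral
body-mass ratio of 1.14: a 58% probability that such an ancestor showed
male-biased power.

The same analysis runs from the shell:

```sh
phylopower simulate --n-taxa 79 --seed 3 --out fixture/
phylopower pipeline --tree fixture/tree.nwk --traits fixture/species.csv \
    --clades fixture/clades.json --reps 2000 --seed 2 --out results/
```

writing a regression table, the per-clade ancestral power table, and a
JSON bundle stamped with the config hash, seed, and package version.

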