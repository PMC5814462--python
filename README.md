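# wtcascade

Threshold-driven contagion on weighted networks: a Monte Carlo simulator,
approximate-master-equation (AME) solvers, and cascade-speed analysis for
the monotone weighted threshold model on configuration-model networks.

## The model

A binary-state (susceptible/infected) dynamics runs on an undirected
weighted network. Each node i has strength q_k(i) = Σ_j w_ij, the total
influence it receives from its k neighbours, and partial strength
q_m(i), the same sum restricted to its m infected neighbours. A
susceptible node becomes infected either spontaneously, with probability
p per update, or deterministically as soon as

    q_m >= phi * q_k,        0 < phi < 1,

and infection is permanent. With all weights equal this is the classic
dynamic cascade (Watts-type) model; heterogeneous weights change the
picture qualitatively: the time for a global cascade to emerge depends
*non-monotonically* on the weight heterogeneity, and skewed weight
distributions can stall spreading in partial cascades.

The analytical description groups nodes into classes (**k**, **m**): after
discretising the weight distribution into n types with weights
**w** = (w_1, ..., w_n), a node has k_j edges and m_j infected neighbours
of each type, and q_**k** = **k**·**w**, q_**m** = **m**·**w**. The package
integrates

* the **full AME**: rate equations for the fractions s_{**k**,**m**}(t),
  i_{**k**,**m**}(t) of each class, closed through mean neighbour-infection
  rates beta_j^s, beta_j^i — this yields per-class observables such as the
  aggregated infection rate F_{k,m}(t) and the per-type fractions of edges
  inside the infected cluster (E^II) and on its surface (E^SI);
* the **reduced AME**: because the infection rate is stepwise (p below
  threshold, 1 at or above), the system reduces exactly to n + 1 equations
  for (nu_1, ..., nu_n, rho), where nu_j is the probability that the
  neighbour across a j-type edge of a susceptible node is infected.

Cascade speed is measured by t_a, the first time the infected density
rho(t) reaches 0.75, and by the relative time
t_r = [t_a(0, phi) − t_a(sigma, phi)] / t_a(0, phi) against the unweighted
network. Phase boundaries in the (sigma, phi) plane follow from a
combinatorial argument: the threshold holds with equality on the curves
phi = **m**·**w**(sigma) / **k**·**w**(sigma), one per class.

## Worked example

The benchmark throughout is a 7-regular configuration-model network with
bimodal weights of mean mu = 1: a fraction delta = 0.5 of edges are strong
(w1 = mu + sigma) and the rest weak (w2 = mu − sigma), with p = 2×10⁻⁴.

```python
from wtcascade import DegreeSpec, parameter_sweep

spec = DegreeSpec("regular", N=10_000, k=7)
df = parameter_sweep(spec, sigma_values=[0.0, 0.3, 0.7], phi_values=[0.25],
                     engine="ame", t_max=400.0)
print(df.to_string(index=False))
```

prints

```
 sigma  phi        t_a       t_r  n_finite
   0.0 0.25 114.352847  0.000000         1
   0.3 0.25 148.277557 -0.296667         1
   0.7 0.25  54.638614  0.522193         1
```

At threshold phi = 0.25 the unweighted cascade reaches 75% infection after
114.4 sweeps. Mild heterogeneity (sigma = 0.3) *slows* the cascade by ~30%
(t_r < 0): nodes with two weak infected neighbours no longer reach their
threshold. Strong heterogeneity (sigma = 0.7) *accelerates* it by ~52%
(t_r > 0): a single strong neighbour now suffices for weakly-connected
nodes. Monte Carlo simulation (`engine="mc"`) reproduces these times to
within a few percent at N = 10^4.

The same machinery is available from the shell:

```sh
wtcascade generate --degree regular --k 7 --n-nodes 10000 \
    --weights bimodal --sigma 0.7 --seed 1 --out net.tsv
wtcascade simulate --net net.tsv --phi 0.25 --seed 2 --out traj.csv
wtcascade ame-solve --k 7 --sigma 0.7 --phi 0.25 --full --out ame.csv
wtcascade sweep --engine ame --sigma-grid 0:1:11 --phi-grid 0.1:0.5:9 \
    --seed 3 --out sweep.csv
wtcascade boundaries --k 7 --phi-min 0.05 --phi-max 0.5 --out curves.csv
```

Declarative experiments (YAML) run end to end with
`wtcascade run config.yaml`, writing trajectory/summary CSVs and a
manifest with all seeds and parameters.

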