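# aipid — PID control as active inference

`aipid` is a small scientific library showing, in runnable form, how the
workhorse controller of engineering and of cell biology — the
Proportional–Integral–Derivative (PID) feedback law — falls out of
variational free-energy minimisation when an agent entertains a
deliberately crude linear model of its world. It is aimed at
computational-neuroscience and control researchers who want a concrete,
testable bridge between active inference and classical set-point
regulation.

## The model

The agent represents its sensed variable in *generalised coordinates of
motion*: the value together with its temporal derivatives,
ψ̃ = (ψ, ψ′, ψ″, …). Its generative model is linear at every embedding
order,

    ψ_k  = x_k + z_k                    (observation, noise z_k)
    x_k' = -α (x_k + v_k) + w_k         (dynamics, noise w_k)

with the exogenous causes collapsed onto a prior trajectory η̃ (the
target, e.g. "10 km/h, zero acceleration"). Under the Laplace
approximation the variational free energy is

    F = ½ Σ_k [ π_z_k ε_z_k² + π_w_k ε_w_k² − ln(π_z_k π_w_k) ],
        ε_z_k = ψ_k − μ_k,   ε_w_k = μ_{k+1} + α(μ_k − η_k),

and the agent runs three gradient flows on it:

* **perception**  μ̃̇ = Dμ̃ − ∂F/∂μ̃,
* **action**      ȧ = −∂F/∂a with the reflex-arc assumption ∂ψ_k/∂a = 1,
* **gain adaptation**  a damped second-order flow on the expected sensory
  log-precisions μ_γz (so precisions stay positive by construction).

With strong priors (π_w α² ≫ π_z) and large α the expectations pin to
η̃ and the action flow becomes exactly the *velocity form* of PID,

    u̇ = k_i e + k_p ė + k_d ë,   (k_i, k_p, k_d) = (π_z, π_z', π_z″),

so the PID gains *are* sensory precisions — which the agent can then tune
online by estimating how precise its sensors actually are. Two embedding
orders give PI control (used in the cruise-control experiments), three
give full PID.

The environment is a cruise-control car with linear drag on a constant
4° slope, sensed through Gaussian noise, subjected to step load
disturbances and set-point changes. The plant dynamics are *not* the
agent's model; regulation survives the mismatch, which is the point.

## Worked example

```bash
python examples/01_disturbance_rejection.py
```

prints

```
disturbance-rejection run (300 s, step load 3 km/h^2 at t = 150 s)
  mean velocity, final 50 s:       10.000 km/h  (prior 10)
  mean acceleration, final 50 s:  0.00002 km/h^2 (prior 0)
  recovery IAE:                     62.74 km/h*s
```

The controller ends the run sitting on its priors (10 km/h, 0 km/h²)
despite the load: the integral character of the order-0 precision has
absorbed the disturbance with no steady-state offset. The integral
absolute error (IAE) integrates |velocity − target| over the excursion
the load caused.

The other examples, one capability each:

* `02_two_degrees_of_freedom.py` — process precisions shape the set-point
  response (settling 2.6 s → 12.2 s as π_w falls through
  e⁻²⁰…e⁻²⁴) while the load response stays invariant (max pointwise
  spread 0.21 km/h).
* `03_gain_adaptation.py` — expected sensory log-precisions climb from −3
  to ≈5.6 against a true sensor log-precision of 5, cutting the recovery
  IAE from ≈63 to ≈1.8 km/h·s.
* `04_ensemble_iae.py` — paired fixed-vs-adapted comparison over randomly
  initialised cars (with the full 20-car condition, adaptation wins
  20/20 with median IAE 50.2 → 0.99 km/h·s).
* `05_pid_equivalence.py` — the action signal matches a classical
  velocity-form PI controller integrated at tight tolerance, with the
  deviation halving as the Euler step halves (ratio 1.98).

A thin CLI wraps the same machinery:

```bash
aipid run --scenario fig2_disturbance --seed 1 --out out/
aipid ensemble --n 20 --seed 7 --out out/
aipid plot --in out/
```

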