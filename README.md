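# qtrgext

Quasi time-reversible Grassmann extrapolation (QTR G-Ext) of SCF guess
densities for Born-Oppenheimer molecular dynamics (BOMD), with the
baselines it is measured against and a self-contained toy electronic
structure so everything is reproducible at desk scale.

## The problem

Every BOMD step re-solves the electronic structure with a self-consistent
field (SCF) iteration; a good initial density guess cuts iteration counts
and hence wall time, but a *biased* guess leaks a systematic error into
the forces and ruins energy conservation in the NVE ensemble.  Converged
one-particle density matrices `D = C C^T` are idempotent rank-`N`
projectors - points on the Grassmann manifold Gr(N, n) - so past densities
cannot be combined linearly.  The cure is to extrapolate on the tangent
space at a fixed reference density `D_0` (mapped back and forth with
SVD-based Grassmann Log/Exp), driven by Coulomb-matrix descriptors `d(R)`
of the nuclear configuration:

    Gamma~_n = sum_{i=1..q~} alpha_i (Gamma_{n-i} + Gamma_{n-q+i}) - Gamma_{n-q}

    alpha = argmin || A alpha - (d_n + d_{n-q}) ||^2 + eps^2 ||alpha||^2,
            A_{.,i} = d_{n-i} + d_{n-q+i},    q~ = floor(q/2)

    D_guess = Exp(Gamma~_n)

The stencil weights past steps symmetrically in time (quasi
time-reversibility), which is what keeps the long-time energy drift at
the level of the dissipative extended-Lagrangian scheme (XLBO) while
needing fewer SCF iterations than both XLBO and the one-sided Grassmann
extrapolation (G-Ext).  All three engines - plus a fully time-reversible
variant and trivial cold-start policies - are implemented behind one
interface and compared by an NVE velocity Verlet driver on a
charge-self-consistent tight-binding toy model whose SCF cost responds to
guess quality the way a Kohn-Sham code's does.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```python
from qtrgext import ToyModelSpec, chain_geometry, compare_report
from qtrgext.diagnostics import render_table
from qtrgext.md import MDConfig, run_bomd

geom = chain_geometry(seed=7)          # 10-atom carbon-like chain, Bohr
spec = ToyModelSpec()                  # t0=1, r0=2, U=0.5, s0=0.1
runs = {}
for strategy in ("qtr", "gext", "xlbo", "fully_tr"):
    cfg = MDConfig(dt=0.5, n_steps=2000, threshold=1e-7, seed=1,
                   strategy=strategy)
    runs[strategy] = run_bomd(geom, cfg, spec).logs
print(render_table(compare_report(runs, q=10)))
```

which prints (1 ps of NVE dynamics per engine, SCF threshold 1e-7):

```
                 stf          ltd  n_windows  mean_iterations  std_iterations
strategy
qtr      6.06931e-05 -2.20717e-09         19          2.28543        0.605617
gext     6.06932e-05  -2.2007e-09         19          2.68543         0.83126
xlbo     6.06931e-05 -2.20676e-09         19              1.7         1.15873
fully_tr 6.06931e-05 -2.20716e-09         19          3.42663        0.554012
```

Reading it: all four engines integrate the same physics (identical
short-time fluctuation ~6.1e-5 Hartree; the drift column sits at the
finite-trajectory regression floor, not at a real secular drift).  The
QTR guess converges the SCF in ~2.3 iterations on average against 2.7
for one-sided G-Ext, and its fully time-reversible variant pays ~1.1
extra iterations for recycling its own guess errors.  XLBO's 1.7 is a
desk-scale artifact of this quasi-harmonic 10-site fixture - its
steady-state tracking error undercuts everything once its cold-start
transient decays; `docs/methods.md` discusses which production-scale
orderings do and do not reproduce at toy scale.

The same machinery is scriptable from the shell:

```sh
qtrgext simulate --config run.json --out out/
qtrgext analyze --logs out/logs.csv --q 5
qtrgext compare --run qtr=out/logs.csv --run xlbo=out2/logs.csv
qtrgext select-params --config run.json
```

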