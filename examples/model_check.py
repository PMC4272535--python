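"""Probabilistically check a specification over a stream of traces.

Checks the shipped chemotaxis specification (statements 9-14) against
on-demand synthetic simulations with the sequential probability ratio
test, in a single pass over the trace stream.
"""

from importlib import resources

from stmc import CallableTraceProvider, CheckerConfig, check_specification
from stmc.cli import synthesize_experiment
from stmc.logic import parse_pblstl

spec_text = resources.files("stmc").joinpath("specs/chemotaxis.pblstl").read_text()
statements = parse_pblstl(spec_text)

provider = CallableTraceProvider(
    lambda i: synthesize_experiment("chemotaxis", seed=100 + i),
    max_traces=40)
# statements with probability bounds close to 0 or 1 (e.g. P < 0.05) need
# an indifference region narrower than their distance to the boundary
cfg = CheckerConfig(method="frequentist_hypothesis", type_i_error=0.05,
                    type_ii_error=0.05, indifference_half_width=0.02)

results = check_specification(statements, provider, cfg)
for i, result in enumerate(results, start=9):
    print(f"statement {i}: {'TRUE' if result.verdict else 'FALSE':5s} "
          f"method={result.method_used:22s} traces={result.n_total:3d} "
          f"(true={result.n_true}, false={result.n_false})")
print(f"traces generated in total: {provider.count}")
print("A TRUE verdict means the probability of the property holding on a")
print("random simulation satisfies the statement's probability bound; when")
print("the 40-trace budget runs out before the SPRT decides, the verdict")
print("falls back to the black-box estimate on the traces seen so far.")
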