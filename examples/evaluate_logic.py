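"""Parse and evaluate spatio-temporal logic formulas on a trace.

Builds a trace from a synthetic chemotaxis run and evaluates bounded
temporal formulas mixing numeric state variables, entity collections,
filters and statistics.
"""

from stmc import Trace, evaluate_blstl, parse_formula
from stmc.cli import synthesize_experiment

experiment = synthesize_experiment("chemotaxis", seed=1)
trace = Trace.from_experiment(experiment)

formulas = [
    # a cluster eventually forms within distance 20 of the attractant centre
    "F [0, 200] (count(filter(clusters, distanceFromOrigin < 20)) > 0)",
    # from some point on, at most two clusters remain
    "F [0, 150] (G [0, 50] (count(clusters) <= 2))",
    # the mean cluster clusteredness eventually rises step over step
    "F [0, 150] (d(mean(clusters, clusteredness)) > 0)",
    # the Silhouette index eventually exceeds 0.6
    "F [0, 200] ({avgClusterednessClusters} > 0.6)",
]
for text in formulas:
    verdict = evaluate_blstl(parse_formula(text), trace, 0)
    print(f"{str(verdict):5s}  {text}")
print("Each line is the truth value of one bounded spatio-temporal property")
print("on this single simulation trace, evaluated from its first state.")
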