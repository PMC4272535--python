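"""Trace providers: where the checker obtains sampled model executions.

A provider yields one trace per request, in a canonical order that makes
checking runs reproducible: lexicographic file-name order for a directory
of STML files, invocation order for an on-demand generator script.
"""

from __future__ import annotations

import subprocess
import tempfile
from pathlib import Path

from .errors import ProviderError, ProviderExhaustedError
from .logic.evaluator import Trace
from .stml import read_stml


class TraceProvider:
    """Iterator-style source of traces; subclasses implement :meth:`next_trace`."""

    #: number of traces loaded/produced so far
    count: int = 0

    def next_trace(self) -> Trace:
        raise NotImplementedError


class DirectoryTraceProvider(TraceProvider):
    """Serves STML files from a directory in lexicographic file-name order."""

    def __init__(self, directory):
        self.directory = Path(directory)
        self.files = sorted(self.directory.glob("*.xml")) \
            + sorted(self.directory.glob("*.stml"))
        self.count = 0

    def __len__(self) -> int:
        return len(self.files)

    def next_trace(self) -> Trace:
        if self.count >= len(self.files):
            raise ProviderExhaustedError(
                f"all {len(self.files)} STML files in {self.directory} consumed"
            )
        experiment = read_stml(self.files[self.count])
        self.count += 1
        return Trace.from_experiment(experiment)


class ScriptTraceProvider(TraceProvider):
    """Runs a user script on demand; one STML file per invocation.

    The script is invoked as ``<command...> --seed S --out PATH`` where the
    per-invocation seed is derived from the master seed and the invocation
    counter (kept below 2**31).
    """

    def __init__(self, command, seed: int = 0, timeout: float | None = None):
        self.command = [command] if isinstance(command, str) else list(command)
        self.seed = int(seed)
        self.timeout = timeout
        self.count = 0

    def next_trace(self) -> Trace:
        invocation_seed = (self.seed + self.count) % (2 ** 31)
        with tempfile.TemporaryDirectory() as tmp:
            out = Path(tmp) / "trace.xml"
            argv = self.command + ["--seed", str(invocation_seed), "--out", str(out)]
            try:
                proc = subprocess.run(argv, capture_output=True, text=True,
                                      timeout=self.timeout)
            except (OSError, subprocess.TimeoutExpired) as exc:
                raise ProviderError(f"generator script failed: {exc}") from exc
            if proc.returncode != 0:
                raise ProviderError(
                    f"generator script exited with {proc.returncode}: "
                    f"{proc.stderr.strip()[:500]}"
                )
            if not out.exists():
                raise ProviderError(
                    f"generator script produced no output file at {out}"
                )
            experiment = read_stml(out)
        self.count += 1
        return Trace.from_experiment(experiment)


class CallableTraceProvider(TraceProvider):
    """Wraps a Python callable ``fn(invocation_index) -> Trace | Experiment``.

    ``max_traces`` makes the provider finite (exhaustion signalled after
    that many requests); in-process counterpart of the script provider.
    """

    def __init__(self, fn, max_traces: int | None = None):
        self.fn = fn
        self.max_traces = max_traces
        self.count = 0

    def next_trace(self) -> Trace:
        if self.max_traces is not None and self.count >= self.max_traces:
            raise ProviderExhaustedError(
                f"callable provider limited to {self.max_traces} traces"
            )
        result = self.fn(self.count)
        self.count += 1
        if isinstance(result, Trace):
            return result
        return Trace.from_experiment(result)
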