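"""Prompt-completion backends and the sliding-window document chunker.

Backends implement a single ``complete_text(prompt) -> str`` method.  The
deterministic :class:`MockBackend` — a mapping from prompt (or its SHA-256
hash) to a canned completion — makes the whole pipeline testable offline;
a live HTTP backend is provided behind the same interface but no part of
the package depends on it.
"""

from __future__ import annotations

import hashlib
import json
import re
import time
from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol

import yaml


class BackendUnavailableError(RuntimeError):
    """All retry attempts against the completion backend failed."""


class BackendTransportError(RuntimeError):
    """A single transport-level failure (retriable)."""


@dataclass
class CompletionConfig:
    """Settings for prompt completion.

    The creativity (temperature-like) setting defaults to the lowest
    supported value: extraction wants the most literal completion, not a
    creative one.
    """

    backend: str = "mock"
    model: str = "gpt-3.5-turbo"
    temperature: float = 0.0
    max_tokens: int = 1024
    timeout: float = 30.0
    retries: int = 2


@dataclass
class CompletionRecord:
    """Provenance for one completion call; ``raw`` is stored verbatim."""

    prompt: str
    raw: str
    backend: str
    wall_time: float = 0.0
    attempts: int = 1


class CompletionBackend(Protocol):
    backend_id: str

    def complete_text(self, prompt: str) -> str: ...


def prompt_key(prompt: str) -> str:
    """Stable hash key for a prompt, used by hashed mock-fixture files."""
    return "sha256:" + hashlib.sha256(prompt.encode("utf-8")).hexdigest()


class MockBackend:
    """Deterministic backend: canned completions keyed by prompt text or prompt hash."""

    backend_id = "mock"

    def __init__(self, completions: Optional[dict[str, str]] = None, fallback: str = ""):
        self.completions = dict(completions or {})
        self.fallback = fallback

    @classmethod
    def from_file(cls, path: str, fallback: str = "") -> "MockBackend":
        """Load a YAML or JSON mapping of prompt (or ``sha256:<hex>``) to completion."""
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
        data = json.loads(text) if path.endswith(".json") else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: mock-completion file must be a mapping")
        return cls({str(k): str(v) for k, v in data.items()}, fallback=fallback)

    def complete_text(self, prompt: str) -> str:
        if prompt in self.completions:
            return self.completions[prompt]
        return self.completions.get(prompt_key(prompt), self.fallback)


class EchoBackend:
    """Identity backend: returns the prompt unchanged (useful for plumbing tests)."""

    backend_id = "echo"

    def complete_text(self, prompt: str) -> str:
        return prompt


class HttpBackend:
    """Minimal JSON-over-HTTP completion client (OpenAI-style chat endpoint).

    Isolated behind the common backend interface; nothing in the package
    or its tests requires network access.
    """

    backend_id = "http"

    def __init__(self, url: str, api_key: str = "", config: Optional[CompletionConfig] = None):
        self.url = url
        self.api_key = api_key
        self.config = config or CompletionConfig(backend="http")

    def complete_text(self, prompt: str) -> str:
        import urllib.error
        import urllib.request

        payload = json.dumps(
            {
                "model": self.config.model,
                "temperature": self.config.temperature,
                "max_tokens": self.config.max_tokens,
                "messages": [{"role": "user", "content": prompt}],
            }
        ).encode("utf-8")
        request = urllib.request.Request(
            self.url,
            data=payload,
            headers={
                "Content-Type": "application/json",
                **({"Authorization": f"Bearer {self.api_key}"} if self.api_key else {}),
            },
        )
        try:
            with urllib.request.urlopen(request, timeout=self.config.timeout) as resp:
                body = json.loads(resp.read().decode("utf-8"))
        except (urllib.error.URLError, OSError, TimeoutError) as exc:
            raise BackendTransportError(str(exc)) from exc
        try:
            return body["choices"][0]["message"]["content"]
        except (KeyError, IndexError, TypeError) as exc:
            raise BackendTransportError(f"unexpected response shape: {body!r}") from exc


def complete(
    prompt: str,
    backend: CompletionBackend,
    config: Optional[CompletionConfig] = None,
) -> CompletionRecord:
    """Run one completion with retries; the returned record holds the verbatim output.

    Transport failures are retried up to ``config.retries`` extra times;
    exhaustion raises :class:`BackendUnavailableError`.  An empty
    completion is not an error — parsing an empty completion simply yields
    an empty instance.
    """
    config = config or CompletionConfig()
    start = time.monotonic()
    last_exc: Optional[Exception] = None
    for attempt in range(1, config.retries + 2):
        try:
            raw = backend.complete_text(prompt)
        except BackendTransportError as exc:
            last_exc = exc
            continue
        return CompletionRecord(
            prompt=prompt,
            raw=raw,
            backend=getattr(backend, "backend_id", "unknown"),
            wall_time=time.monotonic() - start,
            attempts=attempt,
        )
    raise BackendUnavailableError(f"backend failed after {config.retries + 1} attempts: {last_exc}")


@dataclass(frozen=True)
class Chunk:
    """One window of a document, with its character span in the source text."""

    start: int
    end: int
    text: str


_BOUNDARY = re.compile(r"[.!?]\s|\n|\s")


def chunk_text(text: str, window: int = 2500, overlap: int = 250) -> list[Chunk]:
    """Split a document into overlapping windows (a sliding-window approach).

    Window starts sit at multiples of ``window - overlap``; each start
    (after the first) is snapped backward to the nearest sentence or
    whitespace break found within the overlap region, so entities are not
    cut mid-word when a break exists.  Every character of ``text`` belongs
    to at least one chunk.
    """
    if overlap < 0 or window <= overlap:
        raise ValueError(f"require window > overlap >= 0, got window={window} overlap={overlap}")
    if len(text) <= window:
        return [Chunk(start=0, end=len(text), text=text)]
    step = window - overlap
    chunks: list[Chunk] = []
    k = 0
    while k * step < len(text):
        start = k * step
        snapped = start
        if start > 0 and overlap > 0:
            region = text[max(0, start - overlap): start]
            best = None
            for m in _BOUNDARY.finditer(region):
                best = m.end()
            if best is not None:
                snapped = max(0, start - overlap) + best
        end = min(start + window, len(text))
        chunks.append(Chunk(start=snapped, end=end, text=text[snapped:end]))
        k += 1
    return chunks


def reconstruct(chunks: list[Chunk]) -> str:
    """Rebuild the original document from chunks by dropping overlapped spans."""
    out: list[str] = []
    covered = 0
    for c in chunks:
        if c.end <= covered:
            continue
        skip = max(0, covered - c.start)
        out.append(c.text[skip:])
        covered = c.end
    return "".join(out)


BackendFactory = Callable[[], CompletionBackend]

_BACKENDS: dict[str, BackendFactory] = {
    "mock": MockBackend,
    "echo": EchoBackend,
}


def register_backend(backend_id: str, factory: BackendFactory) -> None:
    _BACKENDS[backend_id] = factory


def get_backend(backend_id: str) -> CompletionBackend:
    if backend_id not in _BACKENDS:
        raise KeyError(f"no backend registered under {backend_id!r}")
    return _BACKENDS[backend_id]()
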