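"""Language-model client contract, system prompts, and a deterministic mock.

The pipeline delegates two decisions to a chat model behind an
OpenAI-compatible endpoint: (1) extracting phenotypic phrases from a
clinical note and (2) choosing one HPO term from a retrieved candidate
list.  Everything model-facing lives here: the client with bounded JSON
repair, the two system prompts (overridable from plain-text files), and
a deterministic lexicon-driven mock backend so the whole pipeline can be
exercised without any model.
"""

from __future__ import annotations

import json
import logging
import os
import re
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

from .ontology import HP_ID_PATTERN, normalize_phrase

logger = logging.getLogger("phenorag.llm")


class TransportError(RuntimeError):
    """Network/auth failure talking to the model endpoint.

    Carries endpoint and model name; never the API key.
    """


@dataclass
class ModelConfig:
    base_url: str = ""
    model_name: str = "mock"
    api_key_env: str = "PHENORAG_API_KEY"
    temperature: float = 0.0
    max_retries: int = 1
    timeout_s: float = 60.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.temperature <= 2.0:
            raise ValueError(f"temperature must be in [0, 2], got {self.temperature}")
        if self.max_retries < 0:
            raise ValueError("max_retries must be >= 0")


@dataclass
class ModelReply:
    raw_text: str
    parsed: Any
    attempt: int
    ok: bool


# ---------------------------------------------------------------------------
# System prompts.  Reconstructed behavioral contracts, not verbatim published
# prompts; both are configuration and can be overridden from plain-text files.

EXTRACTION_PROMPT = """\
You are a clinical phenotype extraction assistant.

TASK: Read the clinical note supplied by the user and extract every phrase
that describes a phenotypic abnormality of the patient — signs, symptoms,
morphological or functional findings, laboratory or imaging abnormalities.
Copy each phrase verbatim from the note whenever possible.

EXCLUDE:
- negated findings (e.g. "no evidence of seizures", "denies chest pain");
- findings attributed to family members and not to the patient
  (e.g. "her mother had diabetes");
- administrative or demographic details, dates, medications, procedures;
- words that are only components of a syndrome or disease NAME rather than
  observed phenotypes of the patient (e.g. do not extract "pain" from the
  disease name "Congenital Insensitivity to Pain and Anhidrosis").

OUTPUT SCHEMA (strict): reply with a single JSON array of strings and
nothing else, e.g.
["phrase one", "phrase two"]
If the note describes no phenotypic abnormality, reply with [].
"""

ASSIGNMENT_PROMPT = """\
You are a Human Phenotype Ontology (HPO) term assignment assistant.

TASK: The user supplies a JSON object with an extracted clinical phrase,
its surrounding sentence, and a list of candidate HPO terms retrieved by
similarity search (each with id, label, lineage and organ system).
Choose the single candidate whose term best represents the phrase: prefer
the most appropriate and detailed term, i.e. the most distal (most
specific) matching node in the ontology.

CONSTRAINTS:
- You MUST choose an id from the supplied candidate list; never answer
  with an HPO id that is not in the list.
- If no candidate is an acceptable match for the phrase, answer "none".

OUTPUT SCHEMA (strict): reply with a single JSON object and nothing else:
{"id": "HP:NNNNNNN"}
or
{"id": "none"}
"""


def extraction_prompt() -> str:
    """Default system prompt for the phrase-extraction phase."""
    return EXTRACTION_PROMPT


def assignment_prompt() -> str:
    """Default system prompt for the HPO-assignment phase."""
    return ASSIGNMENT_PROMPT


def load_prompt(path: str | Path) -> str:
    """Read a prompt override from a plain-text file."""
    return Path(path).read_text(encoding="utf-8")


# ---------------------------------------------------------------------------
# Reply parsing


_FENCE = re.compile(r"```(?:json)?\s*(.*?)```", flags=re.S)


def extract_json_payload(text: str) -> Any:
    """Pull the first valid JSON array/object out of a model reply.

    Accepts a bare payload, a fenced code block, or a payload embedded in
    surrounding prose.  Returns ``None`` if nothing parses.
    """
    text = text.strip()
    try:
        return json.loads(text)
    except json.JSONDecodeError:
        pass
    for block in _FENCE.findall(text):
        try:
            return json.loads(block.strip())
        except json.JSONDecodeError:
            continue
    decoder = json.JSONDecoder()
    for i, ch in enumerate(text):
        if ch in "[{":
            try:
                payload, _ = decoder.raw_decode(text[i:])
                return payload
            except json.JSONDecodeError:
                continue
    return None


def validate_phrase_list(payload: Any) -> list[str] | None:
    if isinstance(payload, list) and all(isinstance(p, str) for p in payload):
        return payload
    return None


def validate_choice(payload: Any) -> str | None:
    """Accept ``{"id": "HP:NNNNNNN"}``, ``{"id": "none"}`` or a bare string."""
    value = payload.get("id") if isinstance(payload, dict) else payload
    if not isinstance(value, str):
        return None
    value = value.strip()
    if value.lower() == "none" or HP_ID_PATTERN.match(value):
        return value
    return None


# ---------------------------------------------------------------------------
# Client

Transport = Callable[[str, str], str]  # (system_prompt, user_content) -> raw text

_REPAIR_INSTRUCTION = (
    "\n\nYour previous reply could not be parsed against the required JSON "
    "schema. Reply again with ONLY the JSON payload, no prose.\n"
    "Previous reply was:\n{bad}"
)


class LlmClient:
    """Chat client with strict JSON validation and bounded repair.

    A parse failure triggers up to ``config.max_retries`` re-prompts, each
    appending the schema reminder and the invalid output; the final
    failure returns a marker reply (``ok=False``), never an exception, so
    batch runs cannot stall on one bad reply.
    """

    def __init__(self, config: ModelConfig, transport: Transport):
        self.config = config
        self.transport = transport

    def chat(
        self,
        system_prompt: str,
        user_content: str,
        validate: Callable[[Any], Any] = lambda payload: payload,
        phase: str = "chat",
    ) -> ModelReply:
        content = user_content
        raw = ""
        for attempt in range(self.config.max_retries + 1):
            raw = self.transport(system_prompt, content)
            payload = extract_json_payload(raw)
            parsed = validate(payload) if payload is not None else None
            self._log(phase, attempt, parsed is not None)
            if parsed is not None:
                return ModelReply(raw_text=raw, parsed=parsed, attempt=attempt, ok=True)
            content = user_content + _REPAIR_INSTRUCTION.format(bad=raw[:2000])
        return ModelReply(
            raw_text=raw, parsed=None, attempt=self.config.max_retries, ok=False
        )

    def _log(self, phase: str, attempt: int, parsed_ok: bool) -> None:
        logger.info(
            "%s",
            json.dumps(
                {
                    "phase": phase,
                    "model_name": self.config.model_name,
                    "attempt": attempt,
                    "parse_ok": parsed_ok,
                },
                sort_keys=True,
            ),
        )


class OpenAIChatTransport:
    """Minimal OpenAI-compatible chat-completions transport (stdlib only).

    The API key is read from the environment at call time and is never
    included in log lines or exception messages.
    """

    def __init__(self, config: ModelConfig):
        if not config.base_url:
            raise ValueError("base_url is required for the OpenAI transport")
        self.config = config

    def __call__(self, system_prompt: str, user_content: str) -> str:
        cfg = self.config
        body = json.dumps(
            {
                "model": cfg.model_name,
                "temperature": cfg.temperature,
                "messages": [
                    {"role": "system", "content": system_prompt},
                    {"role": "user", "content": user_content},
                ],
            }
        ).encode("utf-8")
        url = cfg.base_url.rstrip("/") + "/chat/completions"
        request = urllib.request.Request(
            url,
            data=body,
            headers={
                "Content-Type": "application/json",
                "Authorization": f"Bearer {os.environ.get(cfg.api_key_env, '')}",
            },
        )
        try:
            with urllib.request.urlopen(request, timeout=cfg.timeout_s) as resp:
                reply = json.loads(resp.read().decode("utf-8"))
        except (urllib.error.URLError, OSError, json.JSONDecodeError) as exc:
            raise TransportError(
                f"chat request to {url} (model {cfg.model_name}) failed: "
                f"{type(exc).__name__}"
            ) from exc
        try:
            return reply["choices"][0]["message"]["content"]
        except (KeyError, IndexError, TypeError) as exc:
            raise TransportError(
                f"malformed completion payload from {url} (model {cfg.model_name})"
            ) from exc


# ---------------------------------------------------------------------------
# Deterministic mock backend


class MockBackend:
    """Lexicon-driven transport standing in for a chat model in tests.

    Extraction calls (user content = the raw note) return every lexicon
    phrase found verbatim, case-insensitively, in the note, ordered by
    first occurrence.  Assignment calls (user content = a JSON object with
    a ``candidates`` key) return the highest-similarity candidate whose
    HPO id matches the lexicon entry for the phrase, falling back to the
    rank-1 candidate.  Every call is recorded in ``calls``.
    """

    def __init__(self, lexicon: dict[str, str] | None = None):
        self.lexicon = {normalize_phrase(k): v for k, v in (lexicon or {}).items()}
        self.calls: list[dict[str, str]] = []

    def __call__(self, system_prompt: str, user_content: str) -> str:
        payload = None
        try:
            payload = json.loads(user_content)
        except json.JSONDecodeError:
            pass
        if isinstance(payload, dict) and "candidates" in payload:
            self.calls.append({"phase": "assign", "phrase": payload.get("phrase", "")})
            return self._assign(payload)
        self.calls.append({"phase": "extract", "note": user_content[:80]})
        return self._extract(user_content)

    def _extract(self, note: str) -> str:
        low = note.lower()
        found = []
        for phrase in self.lexicon:
            pos = low.find(phrase)
            if pos >= 0:
                found.append((pos, note[pos : pos + len(phrase)]))
        found.sort()
        return json.dumps([text for _, text in found])

    def _assign(self, payload: dict) -> str:
        candidates = payload["candidates"]
        if not candidates:
            return json.dumps({"id": "none"})
        target = self.lexicon.get(normalize_phrase(payload.get("phrase", "")))
        matching = [c for c in candidates if c.get("hpo_id") == target]
        if matching:
            choice = max(matching, key=lambda c: c.get("similarity", 0.0))
        else:
            choice = min(candidates, key=lambda c: c.get("rank", 1))
        return json.dumps({"id": choice["hpo_id"]})


@dataclass
class ScriptedBackend:
    """Transport replaying a fixed sequence of raw replies (for parser and
    adversarial-path tests)."""

    replies: list[str]
    calls: list[tuple[str, str]] = field(default_factory=list)

    def __call__(self, system_prompt: str, user_content: str) -> str:
        self.calls.append((system_prompt, user_content))
        index = min(len(self.calls) - 1, len(self.replies) - 1)
        return self.replies[index]
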