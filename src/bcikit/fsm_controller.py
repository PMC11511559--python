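"""Finite-state controller mapping four decoded thoughts to application
actions.

The four command symbols are LEFT_HAND, RIGHT_HAND, BOTH_HANDS and REST.
A :class:`CommandFSM` is a total deterministic transition table over
(state, command) pairs; stepping it returns the next state plus an action
label.  Actions are plain strings — binding them to a real browser, mail
client or OS explorer is the caller's business, which keeps the controller
testable.

States flagged ``text_entry`` tell the caller to hand control to the P300
speller for free-text input (virtual keyboard mode).

Validation at load time guarantees totality (every state handles every
command) and that MAIN is reachable from every state, so a user can never
get stuck in a sub-application.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd
import yaml

from .eeg_core import MIClass

__all__ = [
    "Command",
    "MI_TO_COMMAND",
    "FSMValidationError",
    "CommandFSM",
    "load_fsm",
    "default_fsm",
    "DEFAULT_TABLE",
    "save_trace",
]


class Command(str, Enum):
    LEFT_HAND = "LEFT_HAND"
    RIGHT_HAND = "RIGHT_HAND"
    BOTH_HANDS = "BOTH_HANDS"
    REST = "REST"


# dataset cursor classes -> thought commands (UP<->both hands, DOWN<->rest)
MI_TO_COMMAND = {
    MIClass.RIGHT: Command.RIGHT_HAND,
    MIClass.LEFT: Command.LEFT_HAND,
    MIClass.BOTH: Command.BOTH_HANDS,
    MIClass.REST: Command.REST,
}


class FSMValidationError(ValueError):
    pass


@dataclass
class CommandFSM:
    states: dict[str, dict]                       # name -> {"text_entry": bool}
    transitions: dict[tuple[str, Command], tuple[str, str]]
    current: str = "MAIN"
    trace: list[tuple[str, str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if "MAIN" not in self.states:
            raise FSMValidationError("FSM must define a MAIN state")
        gaps = [
            (s, c.value)
            for s in self.states
            for c in Command
            if (s, c) not in self.transitions
        ]
        if gaps:
            raise FSMValidationError(f"transition table incomplete; missing {gaps}")
        bad = [
            (s, c.value, t)
            for (s, c), (t, _a) in self.transitions.items()
            if s not in self.states or t not in self.states
        ]
        if bad:
            raise FSMValidationError(f"transitions touch undeclared states: {bad}")
        unreachable = self._states_not_reaching_main()
        if unreachable:
            raise FSMValidationError(f"MAIN unreachable from: {sorted(unreachable)}")
        if self.current not in self.states:
            raise FSMValidationError(f"current state {self.current!r} undeclared")

    def _states_not_reaching_main(self) -> set[str]:
        # reverse-BFS from MAIN over the transition graph
        reverse: dict[str, set[str]] = {s: set() for s in self.states}
        for (src, _c), (dst, _a) in self.transitions.items():
            reverse[dst].add(src)
        seen = {"MAIN"}
        frontier = ["MAIN"]
        while frontier:
            node = frontier.pop()
            for pred in reverse[node]:
                if pred not in seen:
                    seen.add(pred)
                    frontier.append(pred)
        return set(self.states) - seen

    # -- execution ---------------------------------------------------------
    def text_entry(self, state: str | None = None) -> bool:
        """Whether the caller should switch to the P300 speller here."""
        return bool(self.states[state or self.current].get("text_entry", False))

    def step(self, cmd: Command | str) -> tuple[str, str]:
        cmd = Command(cmd)
        src = self.current
        dst, action = self.transitions[(src, cmd)]
        self.current = dst
        self.trace.append((src, cmd.value, dst, action))
        return dst, action

    def run_stream(self, commands) -> list[tuple[str, str, str, str]]:
        """Left-fold of :meth:`step`; returns the trace rows it appended."""
        start = len(self.trace)
        for cmd in commands:
            self.step(cmd)
        return self.trace[start:]

    def reset(self, state: str = "MAIN") -> None:
        if state not in self.states:
            raise FSMValidationError(f"unknown state {state!r}")
        self.current = state
        self.trace = []


# ---------------------------------------------------------------------------
# default table
#
# Only three transitions are fixed by the design brief: from MAIN, the right
# hand launches the browser, the left hand the OS explorer, both hands the
# email client whose inbox opens on another both-hands.  The rest of the
# table is this package's completion: REST backs out toward MAIN, RIGHT_HAND
# cycles a highlight, BOTH_HANDS selects, and compose/address-bar/terminal
# states are text-entry (speller) states.

DEFAULT_TABLE: dict = {
    "states": {
        "MAIN": {},
        "BROWSER": {},
        "BROWSER_ADDRESS": {"text_entry": True},
        "OS_EXPLORER": {},
        "OS_TERMINAL": {"text_entry": True},
        "EMAIL": {},
        "EMAIL_INBOX": {},
        "EMAIL_ITEM": {},
        "EMAIL_COMPOSE": {"text_entry": True},
    },
    "transitions": {
        "MAIN": {
            "RIGHT_HAND": ("BROWSER", "launch_browser"),
            "LEFT_HAND": ("OS_EXPLORER", "launch_os_explorer"),
            "BOTH_HANDS": ("EMAIL", "launch_email"),
            "REST": ("MAIN", "noop"),
        },
        "BROWSER": {
            "RIGHT_HAND": ("BROWSER", "next_link"),
            "LEFT_HAND": ("BROWSER", "previous_link"),
            "BOTH_HANDS": ("BROWSER_ADDRESS", "open_address_bar"),
            "REST": ("MAIN", "close_browser"),
        },
        "BROWSER_ADDRESS": {
            "RIGHT_HAND": ("BROWSER_ADDRESS", "noop"),
            "LEFT_HAND": ("BROWSER_ADDRESS", "noop"),
            "BOTH_HANDS": ("BROWSER", "navigate_to_address"),
            "REST": ("BROWSER", "cancel_address"),
        },
        "OS_EXPLORER": {
            "RIGHT_HAND": ("OS_EXPLORER", "next_entry"),
            "LEFT_HAND": ("OS_TERMINAL", "open_terminal"),
            "BOTH_HANDS": ("OS_EXPLORER", "open_entry"),
            "REST": ("MAIN", "close_os_explorer"),
        },
        "OS_TERMINAL": {
            "RIGHT_HAND": ("OS_TERMINAL", "noop"),
            "LEFT_HAND": ("OS_TERMINAL", "noop"),
            "BOTH_HANDS": ("OS_TERMINAL", "run_command"),
            "REST": ("OS_EXPLORER", "close_terminal"),
        },
        "EMAIL": {
            "RIGHT_HAND": ("EMAIL", "next_folder"),
            "LEFT_HAND": ("EMAIL", "previous_folder"),
            "BOTH_HANDS": ("EMAIL_INBOX", "open_inbox"),
            "REST": ("MAIN", "close_email"),
        },
        "EMAIL_INBOX": {
            "RIGHT_HAND": ("EMAIL_INBOX", "next_message_action"),
            "LEFT_HAND": ("EMAIL_INBOX", "previous_message_action"),
            "BOTH_HANDS": ("EMAIL_ITEM", "open_message"),
            "REST": ("EMAIL", "back_to_folders"),
        },
        "EMAIL_ITEM": {
            "RIGHT_HAND": ("EMAIL_ITEM", "next_item_action"),
            "LEFT_HAND": ("EMAIL_ITEM", "previous_item_action"),
            "BOTH_HANDS": ("EMAIL_COMPOSE", "reply"),
            "REST": ("EMAIL_INBOX", "back_to_inbox"),
        },
        "EMAIL_COMPOSE": {
            "RIGHT_HAND": ("EMAIL_COMPOSE", "noop"),
            "LEFT_HAND": ("EMAIL_COMPOSE", "noop"),
            "BOTH_HANDS": ("EMAIL_ITEM", "send_message"),
            "REST": ("EMAIL_ITEM", "discard_draft"),
        },
    },
}


def _fsm_from_dict(table: dict, start: str = "MAIN") -> CommandFSM:
    try:
        states_raw = table["states"]
        trans_raw = table["transitions"]
    except (KeyError, TypeError):
        raise FSMValidationError("table must define 'states' and 'transitions'")
    states = {
        name: dict(attrs or {}) for name, attrs in states_raw.items()
    }
    transitions: dict[tuple[str, Command], tuple[str, str]] = {}
    for src, row in trans_raw.items():
        for cmd_name, entry in row.items():
            try:
                cmd = Command(cmd_name)
            except ValueError:
                raise FSMValidationError(f"unknown command {cmd_name!r} in state {src}")
            if isinstance(entry, dict):
                dst, action = entry["to"], entry.get("action", "noop")
            else:
                dst, action = entry
            transitions[(src, cmd)] = (str(dst), str(action))
    return CommandFSM(states=states, transitions=transitions, current=start)


def default_fsm() -> CommandFSM:
    """The shipped default controller table."""
    return _fsm_from_dict(DEFAULT_TABLE)


def load_fsm(path: str | Path, start: str = "MAIN") -> CommandFSM:
    """Load and validate an FSM table from YAML.

    Schema::

        states:
          MAIN: {}
          COMPOSE: {text_entry: true}
        transitions:
          MAIN:
            RIGHT_HAND: {to: BROWSER, action: launch_browser}
            ...
    """
    with open(path) as fh:
        table = yaml.safe_load(fh)
    return _fsm_from_dict(table, start=start)


def save_trace(trace: list[tuple[str, str, str, str]], path: str | Path) -> None:
    pd.DataFrame(
        trace, columns=["state", "command", "next_state", "action"]
    ).to_csv(path, sep="\t", index=False)
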