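"""Run configuration: paths, compatibility-table overrides, URI bases and
parser strictness, loadable from a YAML file and fully serialisable so a
run report can embed the effective settings."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .publish import ProviderConfig, UriConfig
from .reconcile import CompatibilityTable, DEFAULT_COMPAT_RULES
from .wikitext import DEFAULT_DISAMBIG_TEMPLATES, DEFAULT_TAXOBOX_ALIASES


@dataclass
class RunConfig:
    taxdump_dir: str = ""
    wiki_dump: str = ""
    output_dir: str = "out"
    compat_rules: dict[str, list[int]] = field(
        default_factory=lambda: {k: sorted(v)
                                 for k, v in DEFAULT_COMPAT_RULES.items()})
    uri_base: str = UriConfig.base
    wikipedia_base: str = UriConfig.wikipedia
    dbpedia_base: str = UriConfig.dbpedia
    provider_id: int = ProviderConfig.provider_id
    provider_name: str = ProviderConfig.name
    snippet_chars: int = 300
    max_redirect_depth: int = 8
    strict: bool = True
    taxobox_aliases: list[str] = field(
        default_factory=lambda: list(DEFAULT_TAXOBOX_ALIASES))
    disambig_templates: list[str] = field(
        default_factory=lambda: sorted(DEFAULT_DISAMBIG_TEMPLATES))
    seed: int = 0

    def compat_table(self) -> CompatibilityTable:
        return CompatibilityTable(
            rules={k: frozenset(v) for k, v in self.compat_rules.items()})

    def uri_config(self) -> UriConfig:
        return UriConfig(base=self.uri_base, wikipedia=self.wikipedia_base,
                         dbpedia=self.dbpedia_base)

    def provider_config(self) -> ProviderConfig:
        return ProviderConfig(provider_id=self.provider_id,
                              name=self.provider_name,
                              name_abbr=self.provider_name)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return replace(cls(), **data)
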