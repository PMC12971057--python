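import random

import pytest

from metallomine import default_registry, default_rule
from metallomine.rule_engine import And, CdsScope, Identifier, Not, Or, RuleExpr


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def rule():
    return default_rule()


# ---------------------------------------------------------------------------
# Independent brute-force rule evaluator (oracle): renders the AST to a
# Python boolean expression with identifier truth values substituted, and
# lets the Python interpreter evaluate it. cds() scopes are expanded by
# explicit enumeration over genes.


def brute_force(expr: RuleExpr, gene_profiles: dict[str, set]) -> bool:
    region = set().union(*gene_profiles.values()) if gene_profiles else set()

    def render(node: RuleExpr, scope: set) -> str:
        if isinstance(node, Identifier):
            return str(node.name in scope)
        if isinstance(node, Not):
            return f"(not {render(node.child, scope)})"
        if isinstance(node, And):
            return f"({render(node.left, scope)} and {render(node.right, scope)})"
        if isinstance(node, Or):
            return f"({render(node.left, scope)} or {render(node.right, scope)})"
        if isinstance(node, CdsScope):
            val = any(
                eval(render(node.child, profs))  # noqa: S307 - test oracle
                for profs in gene_profiles.values()
            )
            return str(val)
        raise TypeError(node)

    return bool(eval(render(expr, region)))  # noqa: S307 - test oracle


def random_ast(rng: random.Random, idents: list[str], depth: int = 3,
               allow_cds: bool = True) -> RuleExpr:
    """Random rule AST over the given identifier pool."""
    if depth <= 0:
        return Identifier(rng.choice(idents))
    kind = rng.choice(["ident", "not", "and", "or", "cds"] if allow_cds
                      else ["ident", "not", "and", "or"])
    if kind == "ident":
        return Identifier(rng.choice(idents))
    if kind == "not":
        return Not(random_ast(rng, idents, depth - 1, allow_cds))
    if kind == "cds":
        return CdsScope(random_ast(rng, idents, depth - 1, allow_cds=False))
    left = random_ast(rng, idents, depth - 1, allow_cds)
    right = random_ast(rng, idents, depth - 1, allow_cds)
    return And(left, right) if kind == "and" else Or(left, right)


def random_assignment(rng: random.Random, idents: list[str]) -> dict[str, set]:
    """1-3 genes, each carrying a random subset of the identifier pool."""
    n_genes = rng.randint(1, 3)
    return {
        f"g{i}": {x for x in idents if rng.random() < 0.4}
        for i in range(n_genes)
    }
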