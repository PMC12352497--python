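# File format reference

## GROMACS-style XVG input

An XVG document consists of:

* metadata lines starting with `@` (Grace directives);
* comment lines starting with `#` (ignored wherever they appear);
* whitespace-separated numeric data rows, all with the same column
  count (column 0 is time in ps).  Any other line is a hard format
  error — corrupted files must not parse.

Recognized metadata:

* `@ subtitle "..."` — searched for the temperature pattern
  `T = <float> (K)`; required unless a temperature override is given.
* `@ s<i> legend "..."` — column labels for data columns 1…; indices
  must be dense.

Grace escape sequences are stripped before matching legends, with the
regex

    \\x[^\\]*\\f\{\}|\\[sSnN]

(`\xl\f{}` renders λ, `\xD\f{}` renders Δ, `\s…\N`/`\S…\N` switch
scripts).  After stripping:

* **Gradient columns** match
  `dH/d\S*\s+(?P<name>[A-Za-z0-9_\-]+)\s*=\s*(?P<value>[-+0-9.eE]+)`
  e.g. `dH/d fep-lambda = 0.25` — the component name labels the
  gradient column and the value gives the window's λ for it.
* **Reduced-potential columns** match
  `\bto\s+(?P<target>\([^)]*\)|[-+0-9.eE]+)\s*$`
  e.g. `ΔH λ to 0.25` or `… to (0.25, 1.00)` — the tail identifies the
  evaluated target state (one float per λ-component, parenthesized and
  comma-separated when there are several).  Duplicate targets are a
  format error.

The sampling state of a u_nk file comes from its dH/dλ legends when
present, otherwise from `name = value` pairs in the subtitle.  Energies
are assumed to be kJ/mol (the GROMACS convention; overridable) and are
converted to kT on ingestion.  Time is taken as ps and never rescaled.

## alchest CSV dialect (v1)

Line-oriented, plain text, comma-separated:

    #alchest <kind> v1          kind ∈ {dhdl, u_nk}
    #meta temperature=<float>   Kelvin (required)
    #meta energy_unit=<tag>     kT | kJ/mol | kcal/mol (default kT)
    #meta lambda_names=<n1,n2>  ordered λ-component names (required)
    <header row>
    <numeric rows…>

Header rows:

* `dhdl`: `time,<n1>,…,<nC>,dHdl_<n1>,…,dHdl_<nC>` — time, the
  sampling-state λ values, then one gradient column per component.
* `u_nk`: `time,<n1>,…,<nC>,u(<v>),u(<v>),…` — time, sampling-state λ
  values, then one column per evaluated state labeled
  `u(<v1>|<v2>|…)` with the state's component values `|`-separated.

All numbers are written with 17 significant digits (`%.17g`), which is
exact for IEEE doubles, so `parse_csv(write_csv(t))` reproduces `t`
bit-for-bit after canonical formatting.  Files in units other than kT
are converted to kT on read using the `#meta` temperature.  Additional
`#`-comment lines are permitted and ignored.
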