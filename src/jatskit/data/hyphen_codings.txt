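# Dash/hyphen/minus characters unified to the plain hyphen-minus "-".
# One hexadecimal code point per line; comments start with '#'.
2010	HYPHEN
2011	NON-BREAKING HYPHEN
2012	FIGURE DASH
2013	EN DASH
2014	EM DASH
2015	HORIZONTAL BAR
2043	HYPHEN BULLET
2212	MINUS SIGN
2796	HEAVY MINUS SIGN
FE58	SMALL EM DASH
FE63	SMALL HYPHEN-MINUS
FF0D	FULLWIDTH HYPHEN-MINUS
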