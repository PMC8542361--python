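# Character codings unified to a plain space (U+0020).
# One hexadecimal code point per line; comments start with '#'.
0009	CHARACTER TABULATION
000B	LINE TABULATION
0085	NEXT LINE
00A0	NO-BREAK SPACE
1680	OGHAM SPACE MARK
180E	MONGOLIAN VOWEL SEPARATOR
2000	EN QUAD
2001	EM QUAD
2002	EN SPACE
2003	EM SPACE
2004	THREE-PER-EM SPACE
2005	FOUR-PER-EM SPACE
2006	SIX-PER-EM SPACE
2007	FIGURE SPACE
2008	PUNCTUATION SPACE
2009	THIN SPACE
200A	HAIR SPACE
200B	ZERO WIDTH SPACE
2028	LINE SEPARATOR
2029	PARAGRAPH SEPARATOR
202F	NARROW NO-BREAK SPACE
205F	MEDIUM MATHEMATICAL SPACE
3000	IDEOGRAPHIC SPACE
FEFF	ZERO WIDTH NO-BREAK SPACE
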