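# Alias -> canonical country name (tab separated); matching is case-insensitive,
# so all-caps forms (UNITED STATES, CHINA, ...) need no separate entry.
USA	United States
U.S.A.	United States
U.S.A	United States
U.S.	United States
US	United States
United States of America	United States
America	United States
UK	United Kingdom
U.K.	United Kingdom
Great Britain	United Kingdom
Britain	United Kingdom
England	United Kingdom
Scotland	United Kingdom
Wales	United Kingdom
Northern Ireland	United Kingdom
People's Republic of China	China
Peoples Republic of China	China
People's Rep. of China	China
Peoples Rep. of China	China
P.R. China	China
P. R. China	China
PR China	China
P.R.China	China
Mainland China	China
Republic of Korea	South Korea
Korea	South Korea
S. Korea	South Korea
Korea, Republic of	South Korea
Democratic People's Republic of Korea	North Korea
DPR Korea	North Korea
Russian Federation	Russia
USSR	Russia
Republic of China	Taiwan
Taiwan, ROC	Taiwan
ROC	Taiwan
Czechia	Czech Republic
Czechoslovakia	Czech Republic
Slovak Republic	Slovakia
The Netherlands	Netherlands
Holland	Netherlands
Deutschland	Germany
Federal Republic of Germany	Germany
Espana	Spain
España	Spain
Islamic Republic of Iran	Iran
Iran, Islamic Republic of	Iran
Viet Nam	Vietnam
Lao PDR	Laos
Lao People's Democratic Republic	Laos
Burma	Myanmar
Cote d'Ivoire	Ivory Coast
Côte d'Ivoire	Ivory Coast
Swaziland	Eswatini
Macedonia	North Macedonia
FYROM	North Macedonia
UAE	United Arab Emirates
Kingdom of Saudi Arabia	Saudi Arabia
KSA	Saudi Arabia
Brasil	Brazil
Türkiye	Turkey
Turkiye	Turkey
Republic of Ireland	Ireland
Syrian Arab Republic	Syria
Brunei Darussalam	Brunei
Cabo Verde	Cape Verde
East Timor	Timor-Leste
DR Congo	Democratic Republic of the Congo
Congo, Democratic Republic	Democratic Republic of the Congo
Congo	Republic of the Congo
Republic of Moldova	Moldova
Vatican	Vatican City
Holy See	Vatican City
The Gambia	Gambia
United Republic of Tanzania	Tanzania
Bolivarian Republic of Venezuela	Venezuela
Hong Kong SAR	Hong Kong
Hong Kong, China	Hong Kong
Macao	Macau
New Guinea	Papua New Guinea
Western Samoa	Samoa
Méjico	Mexico
Mejico	Mexico
Belgique	Belgium
Italia	Italy
Österreich	Austria
Sverige	Sweden
Norge	Norway
Suomi	Finland
Danmark	Denmark
Polska	Poland
Ellada	Greece
Hellas	Greece
Schweiz	Switzerland
Suisse	Switzerland
Svizzera	Switzerland
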