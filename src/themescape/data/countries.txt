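Afghanistan
Albania
Algeria
Argentina
Armenia
Australia
Austria
Azerbaijan
Bahrain
Bangladesh
Belarus
Belgium
Bolivia
Bosnia and Herzegovina
Botswana
Brazil
Bulgaria
Cambodia
Cameroon
Canada
Chile
China
Colombia
Costa Rica
Croatia
Cuba
Cyprus
Czech Republic
Czechia
Denmark
Ecuador
Egypt
Estonia
Ethiopia
Finland
France
Georgia
Germany
Ghana
Greece
Hong Kong
Hungary
Iceland
India
Indonesia
Iran
Iraq
Ireland
Israel
Italy
Jamaica
Japan
Jordan
Kazakhstan
Kenya
Korea
Kuwait
Latvia
Lebanon
Lithuania
Luxembourg
Malaysia
Malta
Mexico
Mongolia
Morocco
Nepal
Netherlands
New Zealand
Nigeria
North Macedonia
Norway
Oman
Pakistan
Panama
Paraguay
Peru
Philippines
Poland
Portugal
Qatar
Republic of China (Taiwan)
Republic of Korea
Romania
Russia
Russian Federation
Saudi Arabia
Serbia
Singapore
Slovakia
Slovenia
South Africa
South Korea
Spain
Sri Lanka
Sweden
Switzerland
Taiwan
Tanzania
Thailand
Tunisia
Turkey
UK
USA
Uganda
Ukraine
United Arab Emirates
United Kingdom
United States
United States of America
Uruguay
Uzbekistan
Venezuela
Vietnam
Zambia
Zimbabwe
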