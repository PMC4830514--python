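# country	adjectival	demonym
Greece	Greek	Greeks
Turkey	Turkish	Turks
Finland	Finnish	Finns
Japan	Japanese	Japanese
Tunisia	Tunisian	Tunisians
Germany	German	Germans
China	Chinese	Chinese
Sri Lanka	Sri Lankan	Sri Lankans
Peru	Peruvian	Peruvians
Italy	Italian	Italians
Czech Republic	Czech	Czechs
France	French	French
Spain	Spanish	Spaniards
Portugal	Portuguese	Portuguese
United Kingdom	British	Britons
England	English	English
Scotland	Scottish	Scots
Ireland	Irish	Irish
Wales	Welsh	Welsh
Netherlands	Dutch	Dutch
Belgium	Belgian	Belgians
Switzerland	Swiss	Swiss
Austria	Austrian	Austrians
Poland	Polish	Poles
Hungary	Hungarian	Hungarians
Romania	Romanian	Romanians
Bulgaria	Bulgarian	Bulgarians
Serbia	Serbian	Serbs
Croatia	Croatian	Croats
Slovenia	Slovenian	Slovenes
Slovakia	Slovak	Slovaks
Ukraine	Ukrainian	Ukrainians
Russia	Russian	Russians
Belarus	Belarusian	Belarusians
Lithuania	Lithuanian	Lithuanians
Latvia	Latvian	Latvians
Estonia	Estonian	Estonians
Norway	Norwegian	Norwegians
Sweden	Swedish	Swedes
Denmark	Danish	Danes
Iceland	Icelandic	Icelanders
United States	American	Americans
Canada	Canadian	Canadians
Mexico	Mexican	Mexicans
Brazil	Brazilian	Brazilians
Argentina	Argentine	Argentines
Chile	Chilean	Chileans
Colombia	Colombian	Colombians
Venezuela	Venezuelan	Venezuelans
Ecuador	Ecuadorian	Ecuadorians
Bolivia	Bolivian	Bolivians
Uruguay	Uruguayan	Uruguayans
Paraguay	Paraguayan	Paraguayans
Cuba	Cuban	Cubans
Jamaica	Jamaican	Jamaicans
Haiti	Haitian	Haitians
Dominican Republic	Dominican	Dominicans
Guatemala	Guatemalan	Guatemalans
Costa Rica	Costa Rican	Costa Ricans
Panama	Panamanian	Panamanians
India	Indian	Indians
Pakistan	Pakistani	Pakistanis
Bangladesh	Bangladeshi	Bangladeshis
Nepal	Nepalese	Nepalese
Bhutan	Bhutanese	Bhutanese
Myanmar	Burmese	Burmese
Thailand	Thai	Thais
Vietnam	Vietnamese	Vietnamese
Cambodia	Cambodian	Cambodians
Laos	Laotian	Laotians
Malaysia	Malaysian	Malaysians
Singapore	Singaporean	Singaporeans
Indonesia	Indonesian	Indonesians
Philippines	Filipino	Filipinos
South Korea	Korean	Koreans
Korea	Korean	Koreans
North Korea	North Korean	North Koreans
Taiwan	Taiwanese	Taiwanese
Mongolia	Mongolian	Mongolians
Kazakhstan	Kazakh	Kazakhs
Uzbekistan	Uzbek	Uzbeks
Iran	Iranian	Iranians
Iraq	Iraqi	Iraqis
Syria	Syrian	Syrians
Lebanon	Lebanese	Lebanese
Israel	Israeli	Israelis
Jordan	Jordanian	Jordanians
Saudi Arabia	Saudi	Saudis
Yemen	Yemeni	Yemenis
Oman	Omani	Omanis
United Arab Emirates	Emirati	Emiratis
Kuwait	Kuwaiti	Kuwaitis
Qatar	Qatari	Qataris
Bahrain	Bahraini	Bahrainis
Egypt	Egyptian	Egyptians
Libya	Libyan	Libyans
Algeria	Algerian	Algerians
Morocco	Moroccan	Moroccans
Sudan	Sudanese	Sudanese
Ethiopia	Ethiopian	Ethiopians
Kenya	Kenyan	Kenyans
Tanzania	Tanzanian	Tanzanians
Uganda	Ugandan	Ugandans
Nigeria	Nigerian	Nigerians
Ghana	Ghanaian	Ghanaians
Senegal	Senegalese	Senegalese
Mali	Malian	Malians
Cameroon	Cameroonian	Cameroonians
Democratic Republic of the Congo	Congolese	Congolese
Angola	Angolan	Angolans
Zambia	Zambian	Zambians
Zimbabwe	Zimbabwean	Zimbabweans
Botswana	Botswanan	Batswana
Namibia	Namibian	Namibians
South Africa	South African	South Africans
Mozambique	Mozambican	Mozambicans
Madagascar	Malagasy	Malagasy
Australia	Australian	Australians
New Zealand	New Zealand	New Zealanders
Fiji	Fijian	Fijians
Papua New Guinea	Papua New Guinean	Papua New Guineans
Greenland	Greenlandic	Greenlanders
Afghanistan	Afghan	Afghans
Armenia	Armenian	Armenians
Azerbaijan	Azerbaijani	Azerbaijanis
Georgia	Georgian	Georgians
Cyprus	Cypriot	Cypriots
Malta	Maltese	Maltese
Luxembourg	Luxembourgish	Luxembourgers
Albania	Albanian	Albanians
North Macedonia	Macedonian	Macedonians
Bosnia and Herzegovina	Bosnian	Bosnians
Montenegro	Montenegrin	Montenegrins
Moldova	Moldovan	Moldovans
Europe	European	Europeans
Africa	African	Africans
Asia	Asian	Asians
North America	North American	North Americans
South America	South American	South Americans
Scandinavia	Scandinavian	Scandinavians
Hispanic	Hispanic	Hispanics
Caucasian	Caucasian	Caucasians
Ashkenazi	Ashkenazi Jewish	Ashkenazi Jews
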