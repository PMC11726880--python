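gene_id	case_000	case_001	case_002	case_003	case_004	case_005	ctrl_000	ctrl_001	ctrl_002	ctrl_003	ctrl_004	ctrl_005
g00000	8.9948168497996654	7.8029946484176751	8.2762388960705611	8.6251795970283425	8.2090501584700935	8.4171404311046736	8.4323545404895448	8.7523545957877023	8.3276580367475468	8.6794156509312632	8.5716949086696186	8.7555699389988355
g00001	9.5753517550418721	10.29172208860569	9.1310420262732208	10.062473643814842	9.2615738477855185	8.9839169745108176	10.068477295690959	9.2431271090000475	9.2690621251426908	8.7685382196308872	8.4137816657512641	9.7800305317287339
g00002	8.1374461057506089	9.1092157893743373	9.6441629420554538	8.662680321469848	8.1567717428701023	8.9171788813999981	9.100943529622004	8.5891841050170523	8.7288115398124901	9.3877146587693012	9.3528052836907349	9.0750684084729549
g00003	5.1070302882009155	5.5133929412425182	5.8416893855071867	5.4342977925152836	5.2352217622941986	5.1575363666860587	5.224226317146127	5.2044283326096519	5.314675033485047	6.113069343733935	5.1399097361283133	5.9836817623466203
g00004	5.1195921859316851	4.9806746978814633	4.4970989279243225	4.6824527489717855	5.8975775255993526	4.9603338112089173	5.1799037290550363	5.2423156717987256	5.4386206273399003	4.7920416736682814	4.6057010694269609	4.8809928682387671
g00005	6.9703848405581343	7.4961328906811131	7.195599734145115	7.2204297598219815	7.1732992578404788	7.7149783728928663	6.8294809422692522	6.8616164714379453	7.5433599307230006	7.0475894775817673	7.2812335752799697	6.7363003672304345
g00006	8.3036919306692276	8.5079432911141897	7.6283080740542681	7.9445593427030428	8.5035576609953143	9.4164304144635906	8.5231693779109676	8.2625665850846435	7.869420764947832	8.4878393448305367	7.0413229974020819	8.2672617254087069
g00007	9.098707870548882	9.0040737409847864	10.42395688865164	8.0270109173125181	9.2526427886029641	9.2982697374626859	7.9974451073211048	6.9629298484147428	7.5304688893697538	7.0160559974048784	7.6999708273454157	7.8617399160806869
g00008	11.297671919694178	11.116423464720928	11.308399826881093	11.304109190933925	11.417962553387937	11.228040968460787	8.8239930451006092	9.3080749996284862	9.8882150769406536	9.2602635958462578	9.3162159272122675	9.7721065431082739
g00009	8.1035005767904202	8.573168730389872	8.3821921539724045	7.9086982988189511	8.1833921979801456	6.6968389543425806	7.7275626326251947	8.0525490553708696	6.932643637887459	7.9650437208743581	8.2520852210237781	8.6437402849068317
g00010	6.6611025073904475	7.4017691809431199	7.2236187217672629	5.6424586289535146	6.3466139458050579	6.381549570932413	8.0054832759207812	7.673274932657999	8.2648370431074127	8.3321539423279347	7.1975125618352447	8.4323261767775399
g00011	5.5792425130935195	6.4311660561743231	6.185342739853076	5.8377467439908051	6.8972029167055515	6.3481144509408836	5.9191768031317702	6.0274963303355404	7.1105832920739429	6.6115876172218702	6.3778647328183462	6.0106258991931174
g00012	5.6198152043563407	5.4126650541084995	4.5755299486504617	5.7812600240495939	5.5458092393801337	4.6631221879225411	5.0172614397596842	5.2144422610886396	5.5012810179921763	6.2028553967882374	5.3472863465553635	4.3678040957159423
g00013	9.5515100146236183	9.1425585334337711	8.3552250964784491	8.0857539595690859	8.6944401911453095	9.4157541023128246	8.8474319164162054	9.5264627180085366	9.0860570856626737	9.3184551915054321	9.5780646695463734	9.5160670779962864
g00014	8.0471269329704072	9.537412002370278	7.5847155785691749	8.4793789756918549	8.0625732526215899	9.1684535630036486	6.4181069040341558	6.556303251982742	6.5038628992358642	6.384235554894973	6.7869548672535167	7.1634689929250275
g00015	7.7324705295494098	7.3702729990814033	8.0767189915009627	8.1944202182966155	8.5656287716423236	7.8049715173225884	8.1160807578820098	8.6634058723977407	7.713479615116654	8.1618529482034923	8.0300183188393284	7.4894957672956242
g00016	3.3703088485360295	3.9899704308657746	4.550806107235724	2.7068284922923942	3.8951680050871875	3.9867595531987217	5.5385302720452865	4.7128301119238678	5.0884427572243931	4.6255534909895593	5.2114616982848156	5.5304930135510411
g00017	6.21737508546535	6.45199577828744	6.7710558276287935	6.7001264278717159	6.0105942145328521	7.0266111766352131	6.5838118533715306	6.418742999065512	6.3618493481461247	6.6911902860892081	6.8567053303959948	5.7084243557120917
g00018	4.6266762497564837	4.1986561383775296	5.2832740185499336	5.2545204825574823	4.8874874672655757	4.5139748211763777	5.717163200014058	5.8625575581327682	5.8520274317358245	5.0877402352209931	5.1330752985600014	5.1319462005206535
g00019	4.2684700384392054	3.7222945240628	4.0331354252225502	4.7441171908119255	4.3349717391849696	4.0980893636999411	5.71049339384715	6.7112303394090178	6.579952084016595	6.3875360005642792	5.9247291968154681	5.2314258961534668
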